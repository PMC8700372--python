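time_s,type,team,player_id,x,y
1.0,pass,home,p2,10.0,0.0
2.0,reception,home,p3,18.0,2.0
3.5,pass,home,p3,18.0,2.0
4.5,reception,home,p4,25.0,-3.0
6.0,pass,home,p4,25.0,-3.0
7.0,reception,home,p5,30.0,5.0
8.0,interception,away,p6,31.0,5.0
9.0,pass,away,p6,28.0,4.0
10.0,reception,away,p7,20.0,-1.0
11.0,out_of_bounds,away,p7,15.0,-34.0
14.0,pass,home,p2,-10.0,0.0
15.0,reception,home,p3,-2.0,3.0
18.0,pass,home,p3,-2.0,3.0
19.5,reception,home,p4,8.0,-4.0
21.0,foul,away,p8,8.0,-4.0
24.0,pass,away,p6,-20.0,0.0
25.0,reception,away,p7,-12.0,6.0
27.0,pass,away,p7,-12.0,6.0
28.0,reception,away,p8,-4.0,-2.0
30.0,pass,away,p8,-4.0,-2.0
31.0,reception,away,p9,6.0,8.0
33.0,pass,away,p9,6.0,8.0
34.0,reception,away,p10,18.0,0.0
35.0,goal,away,p10,52.0,0.0
40.0,pass,home,p2,0.0,0.0
40.5,reception,home,p3,5.0,1.0
41.0,pass,home,p3,5.0,1.0
41.5,reception,home,p4,10.0,-1.0
42.0,pass,home,p4,10.0,-1.0
42.5,reception,home,p5,15.0,2.0
44.0,out_of_bounds,home,p5,20.0,34.5
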