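compound,ic50_nM,pic50_exp,pic50_pred,residual,set_label
1,2,8.699,8.906,-0.207,train
2,3,8.523,8.555,-0.032,train
3,4,8.398,8.287,0.111,train
4,4,8.398,7.989,0.409,train
5,5,8.301,8.201,0.100,train
6,5,8.301,8.293,0.008,train
7,6,8.222,8.183,0.039,train
8,9,8.046,7.879,0.167,train
9,15,7.824,7.578,0.246,train
10,16,7.796,7.831,-0.035,train
11,25,7.602,7.790,-0.188,test
12,26,7.585,6.962,0.623,test
13,28,7.553,7.450,0.103,test
14,29,7.538,7.876,-0.338,train
15,34,7.469,7.243,0.226,train
16,42,7.377,7.440,-0.063,train
17,58,7.237,7.165,0.073,train
18,60,7.222,7.582,-0.360,train
19,66,7.180,7.451,-0.271,train
20,71,7.149,6.971,0.178,train
21,300,6.523,6.484,0.039,train
22,300,6.523,6.294,0.229,train
23,310,6.509,7.119,-0.610,test
24,370,6.432,6.197,0.235,train
25,500,6.301,6.467,-0.166,test
26,500,6.301,6.409,-0.108,train
27,620,6.208,6.281,-0.073,train
28,790,6.102,6.272,-0.169,test
29,900,6.046,6.147,-0.101,train
30,1000,6.000,6.036,-0.036,train
31,1100,5.959,6.234,-0.275,train
32,1100,5.959,6.068,-0.109,train
33,1500,5.824,6.062,-0.238,test
34,2000,5.699,5.873,-0.174,train
35,2600,5.585,5.657,-0.072,train
36,3000,5.523,5.405,0.118,train
37,3200,5.495,5.172,0.323,test
38,4170,5.380,5.353,0.027,train
39,4440,5.353,5.432,-0.079,train
40,5500,5.260,5.270,-0.010,train
41,17600,4.754,4.617,0.137,train
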