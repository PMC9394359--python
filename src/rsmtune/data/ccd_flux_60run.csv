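run,space_type,neurons,learning_rate,momentum,epochs,train_function,msecv
1,axial,16,0.16,0.75,1000,trainlm,0.0257
2,factorial,31,0.31,0.6,1000,traingdm,0.9581
3,axial,16,0.16,0.6,850,trainlm,0.0279
4,axial,16,0.16,0.75,700,traingdm,0.1463
5,factorial,31,0.01,0.6,1000,traingdm,0.1027
6,center,16,0.16,0.75,850,trainlm,0.0246
7,axial,16,0.16,0.9,850,trainlm,0.0250
8,factorial,1,0.01,0.6,1000,trainlm,0.0310
9,factorial,1,0.31,0.9,1000,traingdm,0.7342
10,factorial,1,0.01,0.6,700,trainlm,0.0311
11,center,16,0.16,0.75,850,trainlm,0.0243
12,factorial,1,0.31,0.9,1000,trainlm,0.0309
13,center,16,0.16,0.75,850,trainlm,0.0256
14,factorial,31,0.31,0.6,1000,trainlm,0.0251
15,axial,31,0.16,0.75,850,traingdm,0.7759
16,center,16,0.16,0.75,850,traingdm,0.2568
17,factorial,31,0.01,0.9,700,traingdm,0.9892
18,factorial,31,0.01,0.9,1000,traingdm,0.9729
19,factorial,1,0.31,0.6,1000,trainlm,0.0312
20,center,16,0.16,0.75,850,traingdm,0.2548
21,factorial,31,0.31,0.9,1000,trainlm,0.0238
22,factorial,31,0.31,0.9,1000,traingdm,0.9859
23,factorial,31,0.01,0.6,1000,trainlm,0.0250
24,factorial,31,0.01,0.6,700,trainlm,0.0235
25,factorial,31,0.31,0.6,700,traingdm,0.9744
26,factorial,1,0.31,0.6,700,traingdm,0.0312
27,factorial,1,0.01,0.9,700,traingdm,0.1039
28,axial,16,0.01,0.75,850,traingdm,0.0721
29,factorial,31,0.31,0.9,700,traingdm,0.9237
30,center,16,0.16,0.75,850,trainlm,0.0264
31,factorial,1,0.31,0.9,700,trainlm,0.0309
32,factorial,1,0.31,0.6,1000,traingdm,0.0313
33,center,16,0.16,0.75,850,traingdm,0.1818
34,axial,16,0.01,0.75,850,trainlm,0.0243
35,axial,16,0.31,0.75,850,traingdm,0.8620
36,factorial,1,0.01,0.9,1000,trainlm,0.0314
37,axial,16,0.31,0.75,850,trainlm,0.0256
38,center,16,0.16,0.75,850,trainlm,0.0248
39,factorial,1,0.01,0.9,700,trainlm,0.0309
40,axial,31,0.16,0.75,850,trainlm,0.0264
41,center,16,0.16,0.75,850,traingdm,0.1030
42,factorial,31,0.31,0.9,700,trainlm,0.0261
43,factorial,1,0.01,0.9,1000,traingdm,0.1664
44,axial,16,0.16,0.9,850,traingdm,0.1913
45,factorial,1,0.01,0.6,700,traingdm,0.0615
46,axial,16,0.16,0.75,700,trainlm,0.0262
47,axial,1,0.16,0.75,850,traingdm,0.1048
48,axial,16,0.16,0.75,1000,traingdm,0.0863
49,factorial,31,0.01,0.9,1000,trainlm,0.0252
50,axial,1,0.16,0.75,850,trainlm,0.0311
51,factorial,31,0.01,0.6,700,traingdm,0.1022
52,factorial,31,0.31,0.6,700,trainlm,0.0261
53,factorial,1,0.31,0.9,700,traingdm,0.2292
54,center,16,0.16,0.75,850,traingdm,0.1480
55,factorial,1,0.01,0.6,1000,traingdm,0.0412
56,factorial,31,0.01,0.9,700,trainlm,0.0243
57,factorial,1,0.31,0.6,700,trainlm,0.0312
58,center,16,0.16,0.75,850,trainlm,0.0259
59,center,16,0.16,0.75,850,traingdm,0.0266
60,axial,16,0.16,0.6,850,traingdm,0.0306
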