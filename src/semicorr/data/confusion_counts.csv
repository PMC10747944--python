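split,subset,sens,spec,acc,mcc,tp,tn,fp,fn,n
1,active_training,0.9303,0.5459,0.8166,0.5332,868,214,178,65,1325
1,passive_training,0.9193,0.5407,0.7974,0.5117,809,226,192,71,1298
1,calibration,0.9856,0.8842,0.9654,0.8897,1026,229,30,15,1300
1,validation,0.9804,0.8917,0.9614,0.8839,1000,247,30,20,1297
2,active_training,0.9247,0.5639,0.8122,0.5397,847,234,181,69,1331
2,passive_training,0.9461,0.625,0.848,0.6267,843,245,147,48,1283
2,calibration,0.9941,0.9163,0.9781,0.9321,1008,241,22,6,1277
2,validation,0.9858,0.913,0.9707,0.9099,1038,252,24,15,1329
3,active_training,0.9322,0.5427,0.814,0.5342,852,216,182,62,1312
3,passive_training,0.9381,0.5661,0.8285,0.5639,849,214,164,56,1283
3,calibration,0.98,0.878,0.9568,0.8753,980,259,36,20,1295
3,validation,0.9867,0.8545,0.9594,0.8734,1041,235,40,14,1330
4,active_training,0.899,0.5633,0.786,0.5002,783,249,193,88,1313
4,passive_training,0.9237,0.5807,0.8093,0.5533,823,259,187,68,1337
4,calibration,0.9953,0.9558,0.9884,0.9595,1060,216,10,5,1291
4,validation,0.9943,0.931,0.9828,0.9414,1041,216,16,6,1279
5,active_training,0.9147,0.5523,0.796,0.5145,826,243,197,77,1343
5,passive_training,0.9198,0.5381,0.7894,0.5109,791,240,206,69,1306
5,calibration,0.9922,0.9826,0.9905,0.9683,1020,226,4,8,1258
5,validation,0.9972,0.9826,0.9947,0.9815,1080,226,4,3,1313
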