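# fitted values of an independent local-quadratic (loess, degree 2,
# span 0.75, exact/direct surface) reference implementation on the
# fixture generated by numpy default_rng(42): x~U(0.3,0.7,200),
# y = sin(8x) + N(0,0.3). One fitted value per line, input order.
-0.911891718429673
-0.624315832818673
-0.834216321194693
-0.919445804386968
0.366169107546807
-0.61339377751172
-0.917516923675531
-0.905046190261249
0.241186853893485
-0.647209508869225
-0.474510398499827
-0.72201782885174
-0.886341124711621
-0.875488352922785
-0.633291342076738
-0.0888495784280046
-0.810960091420757
0.483023464144053
-0.87059326304314
-0.87591209404075
-0.918607050881854
-0.434780462911948
-0.62545766793313
-0.782962653159941
-0.909559645717202
0.0137825504053477
-0.679081612596495
0.56265391776018
0.148895452368671
-0.913628793529616
-0.922222566665017
-0.633132939999073
-0.363469859300029
-0.473687061998606
-0.684368561891179
0.0305920588367802
0.234697112863278
-0.695542859245899
-0.0878423132361603
-0.906156591982263
-0.620875556827169
-0.865282580953814
-0.920336331766781
-0.328978649147536
-0.865731995484458
-0.891615380021865
-0.514044591520411
-0.265165836962125
-0.913356482834511
0.199706046117864
-0.00320756205120669
0.713032243935141
-0.904504081412411
-0.902850202791569
-0.921625158716032
-0.908244069376439
-0.66387358051123
-0.826163459006177
0.199548758667234
0.29049358208562
-0.90524370807401
-0.687130082357294
-0.822435594216301
-0.916000394748941
-0.87848523865445
-0.809726347825561
-0.816291746370895
-0.306972973818676
0.615439166790182
-0.620008112586869
-0.0497154923163254
-0.560888769814383
-0.840951085464692
-0.10920940111768
0.50475775552792
-0.24616539751177
-0.279400909968833
-0.90077282057696
-0.813943915806549
-0.906378827539961
-0.902476470257832
-0.556229112292915
-0.883709054614222
0.105478113154706
0.648836359405065
0.38178489155745
-0.924008460037798
-0.669779476702489
0.124887937109983
-0.739454659122894
0.155741398485433
-0.919100156596414
-0.638740765951254
-0.499087872617264
-0.300532124219701
-0.874768665973354
-0.452601428236767
0.390893025829349
0.277785095396133
-0.646385456547287
-0.756323450067099
-0.920172263656759
-0.202763494771507
-0.629134039066676
-0.909357228837138
-0.923608662868741
-0.645160226894201
-0.220749464562078
0.3578344249142
-0.76689796357782
-0.657913422674509
-0.0110710956721531
-0.312251241569121
-0.835047859510837
0.0725217893452869
-0.8368180631972
-0.918458702288176
-0.923838098472544
-0.610741838444171
-0.872366071621484
-0.839624752598637
-0.89138009725678
0.403115024917589
-0.576637147217903
0.57149231687415
-0.727905121065462
-0.373659797611987
0.182904945341955
0.331600059726849
-0.842781639677519
0.0932438677252523
-0.725254635473517
-0.836637430648543
-0.415975098814021
-0.845659764711608
0.648456197344852
-0.654113940337652
-0.707141272967907
-0.907074990031792
0.40967288765111
-0.71523089683731
-0.722477966834882
-0.699551781130004
-0.82869544599343
-0.691550181554815
-0.205900859846334
-0.377952352987313
-0.768660908031245
-0.624381621911018
0.653395213202281
-0.871961967279916
-0.777906350886419
0.197951931195105
-0.81028737857534
0.312410354835154
-0.907674763297943
-0.245751790579769
-0.898938960812819
-0.924088176380427
-0.91442569515885
0.315497826747622
-0.742695466682568
-0.0979208067981907
0.588522550583128
-0.811287820974357
-0.474812754871779
-0.868351438868283
-0.888733643168499
-0.34130313856428
-0.666953714691302
-0.272185326470727
-0.760703065933646
-0.174354987738566
-0.703255568581933
0.113509130202717
0.558195569787857
-0.616775771619121
-0.570432115126983
-0.785333460629809
-0.921371715127487
-0.786776413920124
-0.782425398763176
-0.766068944947085
-0.338188834482843
-0.912852765958771
-0.900587954755663
-0.481461734543061
0.365078326013301
-0.921793625700752
-0.193046562196582
-0.701660750508377
-0.1303018452804
0.260512450177339
-0.86695568057154
0.152372897187645
0.0642124085787727
-0.852370342201985
-0.811922344399695
0.00797471013499842
-0.323669316086578
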