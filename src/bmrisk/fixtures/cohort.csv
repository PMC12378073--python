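infant_id,age_days,body_weight_kg,fir_ml_per_kg_day,sample_id
I001,50,3.332237788273249,0.1499769318361181,S001
I002,40,5.072423104356068,0.7256366055605559,S002
I003,17,3.928560523484893,0.001,S003
I004,33,4.333244929212446,0.001,S004
I005,59,3.5937420422633553,0.001,S005
I006,42,4.908579576653072,0.001,S006
I007,51,4.05851052655811,1.8396154703315433,S007
I008,20,4.18447643892392,0.001,S008
I009,33,3.993047867742225,0.2877288031677855,S009
I010,43,4.511663611744644,0.001,S010
I011,19,4.523068401795303,1.195063496259337,S011
I012,31,4.8595808119602655,0.001,S012
I013,45,4.351468398022744,0.15834489350620723,S013
I014,28,5.366435509621362,0.001,S014
I015,58,4.418771800501686,0.7464497385470168,S015
I016,41,4.98116154519896,1.253149756672475,S016
I017,59,4.697377209253935,0.13967173853115872,S017
I018,58,4.7542512541475155,2.021239351375816,S018
I019,50,4.1362499050690635,0.35349231167213924,S019
I020,40,4.260581242553296,0.3921161153702433,S020
I021,71,6.732669174618912,2.3238241791050864,S021
I022,98,6.353019585330859,4.994454718510393,S022
I023,90,6.17176431158869,0.9140133941815028,S023
I024,93,5.464759650180332,1.5273171110810484,S024
I025,87,5.5749852791965955,3.1794001925569497,S025
I026,61,5.602293677328117,0.4064313904145453,S026
I027,111,5.881588599677354,0.001,S027
I028,77,4.944531085759578,0.6338112891088523,S028
I029,85,5.9422741316040995,1.2035656847254734,S029
I030,82,5.776305881264808,0.8015041222504586,S030
I031,113,6.2661197299895335,0.001,S031
I032,71,6.818771617039481,0.5231778406384064,S032
I033,120,5.774604921922313,0.43056747664146056,S033
I034,94,5.6979741591329285,1.6546776731366053,S034
I035,73,6.265145928020132,1.5008900794869418,S035
I036,122,5.8341919432348694,0.14182975235777018,S036
I037,136,7.271471981535246,0.20552219523078513,S037
I038,143,8.695313207118083,0.001,S038
I039,122,9.685895415784453,0.15798352333190085,S039
I040,147,5.9730553169104335,0.23209138651555783,S040
I041,147,6.674024831240324,0.3780724444385358,S041
I042,141,7.336332946099494,0.001,S042
I043,125,6.786937469452465,0.16443565882332864,S043
I044,134,6.846537405399061,0.001,S044
I045,149,6.011644390160094,0.27758910647024415,S045
I046,145,7.2221296324171425,0.6985772881515645,S046
I047,139,7.765930705200727,0.4385003266534837,S047
I048,121,6.591129183949122,0.42793427796183536,S048
I049,135,5.767854146805629,0.07971251201955518,S049
I050,141,8.124340425317676,0.37215238706378057,S050
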