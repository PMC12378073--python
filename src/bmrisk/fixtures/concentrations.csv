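sample_id,analyte,value
S001,CYA,143.90781586228258
S002,CYA,128.02573485697522
S003,CYA,223.62266767050443
S004,CYA,189.50552453146133
S005,CYA,174.50401832279098
S006,CYA,130.67417185534157
S007,CYA,
S008,CYA,140.29569677610976
S009,CYA,135.32469770172014
S010,CYA,167.92195645743587
S011,CYA,
S012,CYA,191.9492553807937
S013,CYA,188.47755162701313
S014,CYA,203.5048085942699
S015,CYA,126.96320170371752
S016,CYA,106.79229944205318
S017,CYA,169.16953727622638
S018,CYA,
S019,CYA,138.36036762018327
S020,CYA,152.7042977799298
S021,CYA,
S022,CYA,
S023,CYA,157.50905876354668
S024,CYA,130.90592108065422
S025,CYA,101.17826181685442
S026,CYA,187.32279619628162
S027,CYA,155.12645713983864
S028,CYA,140.86736984309798
S029,CYA,131.37302654412102
S030,CYA,150.7856756911409
S031,CYA,155.28919601378314
S032,CYA,224.6674601198998
S033,CYA,180.8391594186528
S034,CYA,124.53788534905516
S035,CYA,
S036,CYA,166.16195985171416
S037,CYA,152.16771217073634
S038,CYA,169.14056530848097
S039,CYA,149.38020961221417
S040,CYA,106.83558554452547
S041,CYA,107.89641465065463
S042,CYA,166.92926587737568
S043,CYA,168.92333533647002
S044,CYA,144.0293496851234
S045,CYA,164.41093449991294
S046,CYA,
S047,CYA,162.05770619897083
S048,CYA,
S049,CYA,183.02447114094912
S050,CYA,112.06176921629894
S051,CYA,110.78620519444596
S052,CYA,128.74917361742087
S053,CYA,129.27827244251458
S054,CYA,139.85533414653008
S055,CYA,119.12849491171511
S056,CYA,173.88773043538237
S057,CYA,143.8190467863151
S058,CYA,101.45580051031268
S059,CYA,101.99800990677767
S060,CYA,169.53191035673035
S061,CYA,120.03497625666287
S062,CYA,137.0700640243111
S063,CYA,194.30394079524538
S064,CYA,140.60212264551907
S065,CYA,188.45323248432678
S066,CYA,
S067,CYA,
S068,CYA,165.58040826037202
S069,CYA,
S070,CYA,118.04461457646902
S071,CYA,108.72533392943049
S072,CYA,
S073,CYA,153.38365834201488
S074,CYA,106.89593058076355
S075,CYA,129.43566878215188
S076,CYA,134.69429418276738
S077,CYA,204.44889256952885
S078,CYA,145.95629773912967
S079,CYA,169.84135895036718
S080,CYA,
S081,CYA,
S082,CYA,137.86616188917378
S083,CYA,151.2163359035995
S084,CYA,129.3485762258811
S085,CYA,138.56771537815092
S086,CYA,132.0355364537669
S087,CYA,147.14343280469248
S088,CYA,176.33744823935933
S089,CYA,153.5891999815113
S090,CYA,116.46330942984328
S091,CYA,
S092,CYA,104.83341693432641
S093,CYA,135.35937940517147
S094,CYA,
S095,CYA,148.45655297945427
S096,CYA,117.5669084150748
S097,CYA,163.17432357644702
S098,CYA,127.65588365661873
S099,CYA,118.1703953614197
S100,CYA,125.18101064858487
S001,MEL,90.55928970338721
S002,MEL,122.72509212646024
S003,MEL,
S004,MEL,
S005,MEL,
S006,MEL,
S007,MEL,95.81701666306233
S008,MEL,
S009,MEL,97.38063959223645
S010,MEL,93.30252546300655
S011,MEL,111.7051475929577
S012,MEL,108.44070952591647
S013,MEL,124.00269677850527
S014,MEL,122.68742930303063
S015,MEL,125.29249592796567
S016,MEL,114.54408687801401
S017,MEL,107.68769719155304
S018,MEL,145.21430903481485
S019,MEL,108.25765476075533
S020,MEL,114.0907681102119
S021,MEL,130.03191607853125
S022,MEL,98.19236418202931
S023,MEL,129.66429456004587
S024,MEL,123.66882710412538
S025,MEL,104.73571229020607
S026,MEL,117.51466287274704
S027,MEL,
S028,MEL,92.55038751899204
S029,MEL,112.39030503094234
S030,MEL,114.61108797461387
S031,MEL,
S032,MEL,151.34787597755442
S033,MEL,117.28913281357502
S034,MEL,104.735786906346
S035,MEL,
S036,MEL,102.17061082538476
S037,MEL,113.7076433668447
S038,MEL,
S039,MEL,92.83587224085238
S040,MEL,108.1340978198076
S041,MEL,110.91136288357154
S042,MEL,
S043,MEL,110.19898053798296
S044,MEL,
S045,MEL,132.6083239914525
S046,MEL,123.61873186460053
S047,MEL,159.62008680314676
S048,MEL,121.85829393436617
S049,MEL,100.54732906860866
S050,MEL,105.97667913574385
S051,MEL,94.40061120652041
S052,MEL,160.7358880879819
S053,MEL,98.26192641240077
S054,MEL,
S055,MEL,93.19155521256354
S056,MEL,
S057,MEL,106.45655618919668
S058,MEL,104.27263233899356
S059,MEL,170.82013037528483
S060,MEL,119.04165278266561
S061,MEL,94.88215586031325
S062,MEL,
S063,MEL,108.12166680735345
S064,MEL,
S065,MEL,112.52793787298995
S066,MEL,
S067,MEL,143.5447641701521
S068,MEL,106.42697749444626
S069,MEL,144.63433836597534
S070,MEL,136.48486211851954
S071,MEL,153.64616123772504
S072,MEL,93.63212502953672
S073,MEL,
S074,MEL,
S075,MEL,120.95799740905179
S076,MEL,131.3694578276717
S077,MEL,91.11248369076858
S078,MEL,108.68654454871336
S079,MEL,112.43522754385617
S080,MEL,105.09919582101053
S081,MEL,102.41801521434256
S082,MEL,91.48860677176123
S083,MEL,137.1884917972708
S084,MEL,93.07956600026215
S085,MEL,
S086,MEL,121.49601873567505
S087,MEL,91.58740414001227
S088,MEL,125.88458188337741
S089,MEL,
S090,MEL,101.6403077959045
S091,MEL,108.66285543215582
S092,MEL,135.59830223889352
S093,MEL,
S094,MEL,102.53916990108249
S095,MEL,
S096,MEL,
S097,MEL,92.87443073606278
S098,MEL,96.91478679480448
S099,MEL,113.85283046522116
S100,MEL,95.17897493179333
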