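year,src,dst,coefficient
2000,Topography,HQ,0.03
2000,Topography,NDVI,0.7666666666666667
2000,Topography,HumanDisturbance,-0.016666666666666666
2000,Climate,HQ,0.21
2000,HumanDisturbance,HQ,-0.12
2000,HumanDisturbance,NDVI,-0.1111111111111111
2000,NDVI,HQ,0.09
2010,Topography,HQ,0.18
2010,Topography,NDVI,0.52
2010,Topography,HumanDisturbance,-0.07692307692307693
2010,HumanDisturbance,HQ,-0.13
2010,HumanDisturbance,NDVI,-0.12
2010,NDVI,HQ,0.25
2018,Topography,HQ,0.38
2018,Topography,NDVI,0.44
2018,Topography,HumanDisturbance,-0.13
2018,Topography,Climate,0.8666666666666667
2018,Climate,HQ,-0.17
2018,Climate,NDVI,0.2
2018,HumanDisturbance,HQ,-0.20
2018,HumanDisturbance,NDVI,-0.3
2018,NDVI,HQ,0.1
2020,Topography,HQ,0.36
2020,Topography,NDVI,0.33285714285714285
2020,Topography,HumanDisturbance,-0.13
2020,Topography,Climate,0.5833333333333334
2020,Climate,HQ,-0.10
2020,Climate,NDVI,-0.14285714285714285
2020,HumanDisturbance,HQ,-0.16
2020,HumanDisturbance,NDVI,-0.14285714285714285
2020,NDVI,HQ,0.14
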