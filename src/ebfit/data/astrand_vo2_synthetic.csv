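# SYNTHETIC nomogram reconstruction generated by ebfit.astrand.synthetic_nomogram_frames();
# linear HR-VO2 extrapolation model, NOT a transcription of the published Astrand-Ryhming tables.
sex,work_rate_w,hr_bpm,vo2max_l_min
M,50,120,2.067
M,50,125,1.905
M,50,130,1.767
M,50,135,1.648
M,50,140,1.544
M,50,145,1.452
M,50,150,1.37
M,50,155,1.297
M,50,160,1.232
M,50,165,1.172
M,50,170,1.119
M,75,120,2.759
M,75,125,2.544
M,75,130,2.36
M,75,135,2.2
M,75,140,2.061
M,75,145,1.938
M,75,150,1.829
M,75,155,1.732
M,75,160,1.645
M,75,165,1.565
M,75,170,1.494
M,100,120,3.452
M,100,125,3.183
M,100,130,2.952
M,100,135,2.752
M,100,140,2.578
M,100,145,2.425
M,100,150,2.289
M,100,155,2.167
M,100,160,2.057
M,100,165,1.958
M,100,170,1.869
M,125,120,4.145
M,125,125,3.821
M,125,130,3.544
M,125,135,3.305
M,125,140,3.096
M,125,145,2.911
M,125,150,2.748
M,125,155,2.602
M,125,160,2.47
M,125,165,2.351
M,125,170,2.244
M,150,120,4.838
M,150,125,4.46
M,150,130,4.137
M,150,135,3.857
M,150,140,3.613
M,150,145,3.398
M,150,150,3.207
M,150,155,3.036
M,150,160,2.883
M,150,165,2.744
M,150,170,2.619
M,175,120,5.53
M,175,125,5.098
M,175,130,4.729
M,175,135,4.409
M,175,140,4.13
M,175,145,3.884
M,175,150,3.666
M,175,155,3.471
M,175,160,3.296
M,175,165,3.137
M,175,170,2.993
M,200,120,6.223
M,200,125,5.737
M,200,130,5.321
M,200,135,4.962
M,200,140,4.648
M,200,145,4.371
M,200,150,4.125
M,200,155,3.906
M,200,160,3.709
M,200,165,3.53
M,200,170,3.368
M,225,120,6.916
M,225,125,6.375
M,225,130,5.913
M,225,135,5.514
M,225,140,5.165
M,225,145,4.857
M,225,150,4.585
M,225,155,4.341
M,225,160,4.122
M,225,165,3.923
M,225,170,3.743
M,250,120,7.608
M,250,125,7.014
M,250,130,6.506
M,250,135,6.066
M,250,140,5.682
M,250,145,5.344
M,250,150,5.044
M,250,155,4.776
M,250,160,4.534
M,250,165,4.316
M,250,170,4.118
F,50,120,2.389
F,50,125,2.163
F,50,130,1.977
F,50,135,1.82
F,50,140,1.686
F,50,145,1.571
F,50,150,1.47
F,50,155,1.381
F,50,160,1.303
F,50,165,1.233
F,50,170,1.17
F,75,120,3.189
F,75,125,2.888
F,75,130,2.639
F,75,135,2.43
F,75,140,2.251
F,75,145,2.097
F,75,150,1.963
F,75,155,1.844
F,75,160,1.74
F,75,165,1.646
F,75,170,1.562
F,100,120,3.99
F,100,125,3.614
F,100,130,3.302
F,100,135,3.04
F,100,140,2.816
F,100,145,2.624
F,100,150,2.455
F,100,155,2.307
F,100,160,2.176
F,100,165,2.059
F,100,170,1.954
F,125,120,4.791
F,125,125,4.339
F,125,130,3.965
F,125,135,3.65
F,125,140,3.382
F,125,145,3.15
F,125,150,2.948
F,125,155,2.77
F,125,160,2.613
F,125,165,2.473
F,125,170,2.346
F,150,120,5.591
F,150,125,5.064
F,150,130,4.627
F,150,135,4.26
F,150,140,3.947
F,150,145,3.676
F,150,150,3.441
F,150,155,3.233
F,150,160,3.05
F,150,165,2.886
F,150,170,2.739
F,175,120,6.392
F,175,125,5.789
F,175,130,5.29
F,175,135,4.87
F,175,140,4.512
F,175,145,4.203
F,175,150,3.933
F,175,155,3.697
F,175,160,3.486
F,175,165,3.299
F,175,170,3.131
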