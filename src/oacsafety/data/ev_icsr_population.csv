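axis,level,drug,count
total,icsr,warfarin,41775
total,icsr,acenocumarol,8818
total,icsr,dabigatran,48341
total,icsr,rivaroxaban,101577
total,icsr,apixaban,39741
total,icsr,edoxaban,3897
sex,F,warfarin,19745
sex,F,acenocumarol,4194
sex,F,dabigatran,21284
sex,F,rivaroxaban,45438
sex,F,apixaban,18852
sex,F,edoxaban,1870
sex,M,warfarin,19789
sex,M,acenocumarol,4449
sex,M,dabigatran,23595
sex,M,rivaroxaban,45952
sex,M,apixaban,18692
sex,M,edoxaban,1936
sex,not_specified,warfarin,2241
sex,not_specified,acenocumarol,175
sex,not_specified,dabigatran,3462
sex,not_specified,rivaroxaban,10187
sex,not_specified,apixaban,2197
sex,not_specified,edoxaban,91
age,over_85,warfarin,7132
age,over_85,acenocumarol,1708
age,over_85,dabigatran,7854
age,over_85,rivaroxaban,10819
age,over_85,apixaban,7369
age,over_85,edoxaban,760
age,65_85,warfarin,21240
age,65_85,acenocumarol,5049
age,65_85,dabigatran,24389
age,65_85,rivaroxaban,45197
age,65_85,apixaban,18634
age,65_85,edoxaban,2040
age,18_64,warfarin,8452
age,18_64,acenocumarol,1580
age,18_64,dabigatran,5107
age,18_64,rivaroxaban,20184
age,18_64,apixaban,4501
age,18_64,edoxaban,415
age,under_18,warfarin,325
age,under_18,acenocumarol,46
age,under_18,dabigatran,26
age,under_18,rivaroxaban,108
age,under_18,apixaban,26
age,under_18,edoxaban,5
age,not_specified,warfarin,4626
age,not_specified,acenocumarol,435
age,not_specified,dabigatran,10965
age,not_specified,rivaroxaban,25269
age,not_specified,apixaban,9211
age,not_specified,edoxaban,677
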