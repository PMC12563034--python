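axis,level,drug,count
total,adr,warfarin,81100
total,adr,acenocumarol,17294
total,adr,dabigatran,87140
total,adr,rivaroxaban,172624
total,adr,apixaban,67104
total,adr,edoxaban,6092
seriousness,serious,warfarin,73784
seriousness,serious,acenocumarol,15357
seriousness,serious,dabigatran,81660
seriousness,serious,rivaroxaban,164925
seriousness,serious,apixaban,60991
seriousness,serious,edoxaban,4322
seriousness,non_serious,warfarin,7232
seriousness,non_serious,acenocumarol,1918
seriousness,non_serious,dabigatran,5475
seriousness,non_serious,rivaroxaban,7699
seriousness,non_serious,apixaban,6113
seriousness,non_serious,edoxaban,1770
seriousness,not_specified,warfarin,84
seriousness,not_specified,acenocumarol,19
seriousness,not_specified,dabigatran,5
seriousness,not_specified,rivaroxaban,0
seriousness,not_specified,apixaban,0
seriousness,not_specified,edoxaban,0
outcome,fatal,warfarin,6817
outcome,fatal,acenocumarol,1466
outcome,fatal,dabigatran,10774
outcome,fatal,rivaroxaban,12947
outcome,fatal,apixaban,5878
outcome,fatal,edoxaban,368
outcome,not_recovered,warfarin,5747
outcome,not_recovered,acenocumarol,969
outcome,not_recovered,dabigatran,10882
outcome,not_recovered,rivaroxaban,13382
outcome,not_recovered,apixaban,5129
outcome,not_recovered,edoxaban,841
outcome,not_specified,warfarin,2164
outcome,not_specified,acenocumarol,584
outcome,not_specified,dabigatran,12
outcome,not_specified,rivaroxaban,221
outcome,not_specified,apixaban,0
outcome,not_specified,edoxaban,0
outcome,recovered,warfarin,22603
outcome,recovered,acenocumarol,8123
outcome,recovered,dabigatran,25083
outcome,recovered,rivaroxaban,35182
outcome,recovered,apixaban,10005
outcome,recovered,edoxaban,1728
outcome,recovered_with_sequelae,warfarin,1014
outcome,recovered_with_sequelae,acenocumarol,410
outcome,recovered_with_sequelae,dabigatran,1561
outcome,recovered_with_sequelae,rivaroxaban,2085
outcome,recovered_with_sequelae,apixaban,945
outcome,recovered_with_sequelae,edoxaban,180
outcome,recovering,warfarin,12250
outcome,recovering,acenocumarol,2231
outcome,recovering,dabigatran,3118
outcome,recovering,rivaroxaban,26037
outcome,recovering,apixaban,5337
outcome,recovering,edoxaban,858
outcome,unknown,warfarin,34752
outcome,unknown,acenocumarol,4301
outcome,unknown,dabigatran,40472
outcome,unknown,rivaroxaban,89991
outcome,unknown,apixaban,42020
outcome,unknown,edoxaban,2284
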