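generic_name,brand_names,min_dose_mg,max_dose_mg,frequency_per_day,safe_window_hours,dose_options
acebutolol,N,200,1200,1,4,
acebutolol,N,200,600,2,2,
aliskiren,Tekturna,150,300,1,6,
aliskiren-hct,Tekturna HCT,150-12.5,300-25,1,4,
amiloride,N,5,20,1,4,
amiloride-hct,N,5-50,5-50,1,4,
amlodipine,"Norvasc, Katerzia",2.5,10,1,6,2.5;5;10
amlodipine-atorvastatin,Caduet,2.5-10,10-80,1,6,
amlodipine-benazepril,Lotrel,2.5-10,10-40,1,6,
amlodipine-hct-olmesartan,Tribenzor,5-12.5-20,10-25-40,1,4,
amlodipine-hct-valsartan,Exforge HCT,5-12.5-160,10-25-320,1,4,
amlodipine-olmesartan,Azor,5-20,10-40,1,6,
amlodipine-telmisartan,Twynsta,5-40,10-80,1,6,
amlodipine-valsartan,Exforge,5-160,10-320,1,6,
atenolol,Tenormin,25,100,1,4,
atenolol,Tenormin,25,50,2,2,
atenolol-chlorthalidone,Tenoretic 50 and 100,50-25,100-25,1,4,
azilsartan,Edarbi,40,80,1,6,
azilsartan-chlorthalidone,Edarbyclor,40-12.5,40-25,1,4,
benazepril,Lotensin,5,40,1,6,
benazepril-hct,Lotensin HCT,5-6.25,20-25,1,4,
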