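generic_name,brand_names,min_dose_mg,max_dose_mg,frequency_per_day,safe_window_hours,dose_options
examplol,N,25,100,2,3,25;50;100
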