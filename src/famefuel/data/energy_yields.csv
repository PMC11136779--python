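treatment,carbohydrate,lipid,is_control
control,166.96,153.4,true
Zn-0.2,,176.3,false
Zn-0.4,,226.0,false
Zn-0.6,,212.1,false
Zn-0.8,,114.6,false
Co-1,174.05,191.4,false
Co-2,254.69,230.6,false
Co-3,202.61,283.3,false
Mn-2,73.91,183.8,false
Mn-4,,149.6,false
Mn-6,,111.0,false
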