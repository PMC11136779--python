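sample_id,sfa,mufa,pufa,tfa,low_confidence,note
control,44.56,28.01,0,72.57,false,
Zn-0.2,54.6,28.02,17.25,99.87,false,
Zn-0.4,51.2,39.39,9.33,99.92,false,
Zn-0.6,58.17,38.03,0,96.2,true,printed sum MUFA 38.03 disagrees with per-acid re-sum 38.65
Zn-0.8,50.34,36.28,0,86.6,false,
Co-1,54.35,43.01,2.64,100.0,true,garbled source cell read as C13:0=0.08; SFA re-sum 54.12 vs printed 54.35
Co-2,47.61,44.04,3.18,94.83,false,
Co-3,63.13,19.95,0,83.08,false,
Mn-2,48.76,46.56,3.54,98.86,true,source column misaligned; C15:0-C24:0 reassigned to match dominant-palmitic chemistry
Mn-4,61.38,21.08,1.81,84.64,true,printed sum MUFA 21.08 disagrees with per-acid re-sum 25.91
Mn-6,64.44,25.66,2.64,92.74,true,printed sum PUFA 2.64 disagrees with per-acid re-sum 2.62
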