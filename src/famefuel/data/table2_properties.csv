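sample_id,CN,SV,IV,DU,LCSF,CFPP,CP,PP,OS,FP
control,78.68,143.77,24.49,44.2,8.79,11.15,12.74,7.02,6.07,189.36
Zn-0.2,58.87,203.09,63.38,62.52,7.24,6.26,12.85,7.13,5.37,185.76
Zn-0.4,63.36,184.15,55.68,58.05,8.02,9.1,13.47,7.8,5.54,174.85
Zn-0.6,66.5,194.52,35.0,38.65,5.82,1.8,27.7,21,6.28,150.11
Zn-0.8,63.15,172.8,65.27,36.28,8.0,8.45,1.88,11.5,6.38,177.33
Co-1,63.73,202.71,42.29,48.23,8.43,9.99,15.6,10.11,5.92,172.93
Co-2,64.97,193.71,42.02,50.41,5.21,-0.124,18.63,13.4,5.21,186.13
Co-3,74.91,167.21,17.65,19.95,14.26,28.33,16.59,11.19,7.0,189.47
Mn-2,62.29,205.6,46.67,53.74,5.95,2.22,12.27,6.5,5.7,176.28
Mn-4,69.98,184.17,26.21,24.71,9.99,14.69,12.71,6.99,6.82,175.03
Mn-6,69.74,186.79,25.47,30.94,10.63,16.9,23.2,18.36,6.58,190.12
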