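sample_id,metal,dose,dose_unit,fatty_acid,percent
control,none,,,C16:0,33.72
control,none,,,C18:0,10.84
control,none,,,C16:1 n-7,5.19
control,none,,,C18:1 n-9,22.82
Zn-0.2,Zn,0.2,mM,C6:0,0.35
Zn-0.2,Zn,0.2,mM,C8:0,0.21
Zn-0.2,Zn,0.2,mM,C9:0,0.22
Zn-0.2,Zn,0.2,mM,C10:0,0.70
Zn-0.2,Zn,0.2,mM,C12:0,1.21
Zn-0.2,Zn,0.2,mM,C13:0,1.37
Zn-0.2,Zn,0.2,mM,C14:0,5.14
Zn-0.2,Zn,0.2,mM,C15:0,3.20
Zn-0.2,Zn,0.2,mM,C16:0,33.92
Zn-0.2,Zn,0.2,mM,C17:0,2.69
Zn-0.2,Zn,0.2,mM,C18:0,3.68
Zn-0.2,Zn,0.2,mM,C19:0,0.86
Zn-0.2,Zn,0.2,mM,C20:0,0.10
Zn-0.2,Zn,0.2,mM,C22:0,0.60
Zn-0.2,Zn,0.2,mM,C24:0,0.24
Zn-0.2,Zn,0.2,mM,C30:0,0.11
Zn-0.2,Zn,0.2,mM,C9:1,28.02
Zn-0.2,Zn,0.2,mM,C18:2 n-6,6.78
Zn-0.2,Zn,0.2,mM,C18:4 n-3,10.15
Zn-0.2,Zn,0.2,mM,C20:3 n-3,0.32
Zn-0.4,Zn,0.4,mM,C11:0,0.25
Zn-0.4,Zn,0.4,mM,C14:0,6.75
Zn-0.4,Zn,0.4,mM,C15:0,1.12
Zn-0.4,Zn,0.4,mM,C16:0,35.00
Zn-0.4,Zn,0.4,mM,C18:0,7.15
Zn-0.4,Zn,0.4,mM,C20:0,0.93
Zn-0.4,Zn,0.4,mM,C16:1 n-7,0.41
Zn-0.4,Zn,0.4,mM,C18:1 n-9,38.42
Zn-0.4,Zn,0.4,mM,C20:1,0.56
Zn-0.4,Zn,0.4,mM,C18:2 n-6,3.63
Zn-0.4,Zn,0.4,mM,C18:4 n-3,3.22
Zn-0.4,Zn,0.4,mM,C20:4 n-6,2.48
Zn-0.6,Zn,0.6,mM,C16:0,58.17
Zn-0.6,Zn,0.6,mM,C16:1 n-7,3.86
Zn-0.6,Zn,0.6,mM,C18:1 n-9,34.79
Zn-0.8,Zn,0.8,mM,C8:0,0.10
Zn-0.8,Zn,0.8,mM,C9:0,0.08
Zn-0.8,Zn,0.8,mM,C14:0,1.20
Zn-0.8,Zn,0.8,mM,C16:0,41.58
Zn-0.8,Zn,0.8,mM,C18:0,7.35
Zn-0.8,Zn,0.8,mM,C22:0,0.05
Zn-0.8,Zn,0.8,mM,C16:1 n-7,3.59
Zn-0.8,Zn,0.8,mM,C18:1 n-9,32.69
Co-1,Co,1,uM,C5:0,0.03
Co-1,Co,1,uM,C6:0,0.22
Co-1,Co,1,uM,C8:0,0.03
Co-1,Co,1,uM,C9:0,0.23
Co-1,Co,1,uM,C10:0,0.23
Co-1,Co,1,uM,C11:0,0.23
Co-1,Co,1,uM,C12:0,0.50
Co-1,Co,1,uM,C13:0,0.08
Co-1,Co,1,uM,C14:0,4.12
Co-1,Co,1,uM,C16:0,39.15
Co-1,Co,1,uM,C17:0,1.37
Co-1,Co,1,uM,C18:0,7.15
Co-1,Co,1,uM,C20:0,0.22
Co-1,Co,1,uM,C22:0,0.37
Co-1,Co,1,uM,C24:0,0.03
Co-1,Co,1,uM,C28:0,0.10
Co-1,Co,1,uM,C30:0,0.06
Co-1,Co,1,uM,C9:1,0.09
Co-1,Co,1,uM,C16:1 n-7,5.33
Co-1,Co,1,uM,C18:1 n-9,37.43
Co-1,Co,1,uM,C20:1,0.16
Co-1,Co,1,uM,C18:2 n-6,2.16
Co-1,Co,1,uM,C18:4 n-3,0.10
Co-1,Co,1,uM,C20:4 n-6,0.38
Co-2,Co,2,uM,C16:0,44.90
Co-2,Co,2,uM,C17:0,1.28
Co-2,Co,2,uM,C18:0,1.43
Co-2,Co,2,uM,C16:1 n-7,8.46
Co-2,Co,2,uM,C18:1 n-9,34.27
Co-2,Co,2,uM,C20:1,1.31
Co-2,Co,2,uM,C18:2 n-6,2.15
Co-2,Co,2,uM,C18:4 n-3,0.34
Co-2,Co,2,uM,C20:4 n-6,0.69
Co-3,Co,3,uM,C14:0,7.14
Co-3,Co,3,uM,C16:0,41.03
Co-3,Co,3,uM,C17:0,3.28
Co-3,Co,3,uM,C18:0,7.36
Co-3,Co,3,uM,C22:0,4.32
Co-3,Co,3,uM,C16:1 n-7,7.92
Co-3,Co,3,uM,C18:1 n-9,9.69
Co-3,Co,3,uM,C20:1,2.34
Mn-2,Mn,2,mM,C8:0,0.15
Mn-2,Mn,2,mM,C9:0,0.70
Mn-2,Mn,2,mM,C10:0,0.75
Mn-2,Mn,2,mM,C12:0,6.20
Mn-2,Mn,2,mM,C13:0,0.26
Mn-2,Mn,2,mM,C14:0,0.45
Mn-2,Mn,2,mM,C15:0,2.06
Mn-2,Mn,2,mM,C16:0,32.02
Mn-2,Mn,2,mM,C17:0,0.80
Mn-2,Mn,2,mM,C18:0,3.61
Mn-2,Mn,2,mM,C20:0,0.32
Mn-2,Mn,2,mM,C22:0,0.12
Mn-2,Mn,2,mM,C24:0,0.21
Mn-2,Mn,2,mM,C30:0,0.11
Mn-2,Mn,2,mM,C9:1,0.28
Mn-2,Mn,2,mM,C16:1 n-7,3.57
Mn-2,Mn,2,mM,C18:1 n-9,42.17
Mn-2,Mn,2,mM,C20:1,0.54
Mn-2,Mn,2,mM,C18:2 n-6,3.19
Mn-2,Mn,2,mM,C18:4 n-3,0.26
Mn-2,Mn,2,mM,C20:4 n-6,0.09
Mn-4,Mn,4,mM,C4:0,4.09
Mn-4,Mn,4,mM,C14:0,10.37
Mn-4,Mn,4,mM,C16:0,33.67
Mn-4,Mn,4,mM,C18:0,13.25
Mn-4,Mn,4,mM,C16:1 n-7,9.25
Mn-4,Mn,4,mM,C18:1 n-9,16.66
Mn-4,Mn,4,mM,C18:2 n-6,1.81
Mn-6,Mn,6,mM,C14:0,0.96
Mn-6,Mn,6,mM,C15:0,1.37
Mn-6,Mn,6,mM,C16:0,53.59
Mn-6,Mn,6,mM,C17:0,0.64
Mn-6,Mn,6,mM,C18:0,5.96
Mn-6,Mn,6,mM,C20:0,1.22
Mn-6,Mn,6,mM,C22:0,0.71
Mn-6,Mn,6,mM,C16:1 n-7,8.39
Mn-6,Mn,6,mM,C18:1 n-9,15.88
Mn-6,Mn,6,mM,C20:1,1.39
Mn-6,Mn,6,mM,C18:4 n-3,1.64
Mn-6,Mn,6,mM,C20:4 n-6,0.98
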