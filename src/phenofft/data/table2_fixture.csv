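factor,sample,A,A%,P,FF,EX,C,EC,RI,DMD,DM,G
amplitude,Control,1.18,1.18,0.96,0.68,-0.02,0.89,-1.24,0.70,0.70,1.38,0.60
amplitude,PTX,1.22,1.22,1.03,0.93,1.02,1.00,0.62,1.05,1.05,-0.89,0.59
amplitude,CLC,0.27,0.27,0.38,0.43,0.59,0.41,1.08,0.46,0.46,-0.95,-1.29
amplitude,VBL,0.06,0.06,0.17,0.14,0.31,0.22,0.91,0.91,0.91,1.27,0.59
phase,Control,-0.92,-0.92,-0.91,0.21,0.36,-0.87,1.28,-0.89,-0.89,-1.68,-1.03
phase,PTX,-1.10,-1.10,-1.20,0.04,-0.02,-1.27,-0.87,-0.80,-0.80,1.39,-1.26
phase,CLC,-0.06,-0.06,-0.26,0.38,0.33,-0.45,-0.58,0.46,0.46,0.80,0.86
phase,VBL,0.26,0.26,-0.10,0.41,0.30,-0.27,-0.30,0.42,0.42,0.24,0.71
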