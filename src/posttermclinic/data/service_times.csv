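activity,min,median,mean,max,sd,kurtosis,skewness
Check In,0.130,0.467,0.457,1.000,0.249,2.156,0.531
Connect CTG,2.000,3.341,3.410,5.000,0.863,1.842,0.156
CTG Scan,20.000,25.557,26.250,45.000,4.855,6.011,1.558
Disconnect CTG,2.000,3.341,3.410,5.000,0.863,1.842,0.156
Consultation,10.000,21.282,22.325,45.000,4.901,4.764,1.005
Check out,0.130,1.580,1.589,5.000,0.985,2.696,0.480
No. of CTG checks,0.000,1.897,2.120,10.000,1.462,8.374,1.793
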