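# Packaged femoral standard-thickness reference (mean +/- SD, mm) for a
# healthy cohort aged 20-45, by sex (M man / W woman) and knee side.
sex,side,region,mean_mm,sd_mm
M,LEFT,FMA,2.14,0.29
M,LEFT,FMC,1.97,0.21
M,LEFT,FMP,2.02,0.32
M,LEFT,FLA,1.98,0.19
M,LEFT,FLC,2.00,0.27
M,LEFT,FLP,1.89,0.38
W,LEFT,FMA,1.95,0.35
W,LEFT,FMC,1.92,0.23
W,LEFT,FMP,1.95,0.23
W,LEFT,FLA,1.97,0.18
W,LEFT,FLC,1.88,0.21
W,LEFT,FLP,1.92,0.14
M,RIGHT,FMA,1.98,0.24
M,RIGHT,FMC,2.00,0.23
M,RIGHT,FMP,2.06,0.42
M,RIGHT,FLA,2.30,0.22
M,RIGHT,FLC,2.06,0.27
M,RIGHT,FLP,1.98,0.37
W,RIGHT,FMA,1.91,0.21
W,RIGHT,FMC,1.88,0.20
W,RIGHT,FMP,1.89,0.22
W,RIGHT,FLA,2.01,0.21
W,RIGHT,FLC,1.93,0.18
W,RIGHT,FLP,1.87,0.39
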