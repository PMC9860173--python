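MEME version 4

ALPHABET= ACGT

strands: + -

Background letter frequencies
A 0.25000 C 0.25000 G 0.25000 T 0.25000

MOTIF synth_m1_w3
letter-probability matrix: alength= 4 w= 3 nsites= 1000000 E= 0
 0.394605 0.591443 0.012058 0.001895
 0.152593 0.451388 0.186701 0.209318
 0.231607 0.497997 0.270209 0.000188

MOTIF synth_m2_w5
letter-probability matrix: alength= 4 w= 5 nsites= 1000000 E= 0
 0.150691 0.043418 0.754339 0.051552
 0.039189 0.606488 0.168273 0.186049
 0.014839 0.369626 0.503642 0.111894
 0.598327 0.074734 0.280677 0.046263
 0.195451 0.098024 0.145914 0.560611

MOTIF synth_m3_w6
letter-probability matrix: alength= 4 w= 6 nsites= 1000000 E= 0
 0.083160 0.139668 0.326942 0.450231
 0.407567 0.450071 0.083455 0.058907
 0.154024 0.175159 0.562104 0.108713
 0.177414 0.204434 0.084735 0.533416
 0.350767 0.600423 0.015993 0.032817
 0.021701 0.152512 0.450468 0.375319

MOTIF synth_m4_w8
letter-probability matrix: alength= 4 w= 8 nsites= 1000000 E= 0
 0.027055 0.095204 0.341316 0.536426
 0.301534 0.226558 0.381233 0.090675
 0.205734 0.013820 0.092863 0.687582
 0.065154 0.313273 0.125913 0.495660
 0.317329 0.518880 0.101375 0.062416
 0.000853 0.355339 0.272874 0.370934
 0.272073 0.239246 0.245561 0.243120
 0.011502 0.586033 0.384384 0.018081

MOTIF synth_sharp_w5
letter-probability matrix: alength= 4 w= 5 nsites= 1000000 E= 0
 0.929600 0.023467 0.023467 0.023467
 0.023467 0.929600 0.023467 0.023467
 0.023467 0.023467 0.929600 0.023467
 0.023467 0.023467 0.023467 0.929600
 0.929600 0.023467 0.023467 0.023467

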