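H LEVM760107
D van der Waals parameter (synthetic values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    1.0000  6.1300  2.9500  2.7800  2.4300  3.9500  3.7800  0.0000  4.6600  4.0000
    4.0000  4.7700  4.4300  5.8900  2.7200  1.6000  2.6000  8.0800  6.4700  3.0000
//
H COHE430101
D Partial specific volume (synthetic values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.7400  0.7000  0.6200  0.6000  0.6300  0.6700  0.6600  0.6400  0.6700  0.9000
    0.9000  0.8200  0.7500  0.7700  0.7600  0.6300  0.7000  0.7400  0.7100  0.8600
//
H CHAM820102
D Free energy of solution in water, kcal/mole (synthetic values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.1000 -0.3000 -0.4000 -0.8000  2.2000 -0.2500 -0.6000 -0.2000  0.1500  0.1000
    0.0500 -0.2000 -0.7500  0.4500 -0.7000 -0.3500 -0.1500  2.8000  2.5000  0.0000
//
H FAUJ880112
D Negative charge (synthetic values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.0000  0.0000  0.0000  1.0000  0.0000  0.0000  1.0000  0.0000  0.0000  0.0000
    0.0000  0.0000  0.0000  0.0000  0.0000  0.0000  0.0000  0.0000  0.0000  0.0000
//
H QIAN880115
D Weights for beta-sheet at the window position of -5 (synthetic values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.1200 -0.0800 -0.2100 -0.3300  0.0500 -0.0200 -0.1500 -0.4100  0.0800  0.4400
    0.2800 -0.1200  0.1800  0.3100 -0.5300 -0.1000  0.1400  0.2200  0.3500  0.4900
//
H YUTK870102
D Unfolding Gibbs energy in water, pH9.0 (synthetic values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    7.2000  5.9000  5.1000  4.8000  8.9000  6.0000  5.4000  6.6000  6.1000  8.4000
    8.1000  5.6000  7.7000  8.6000  6.9000  6.2000  6.5000  9.1000  7.9000  8.2000
//
H OOBM850102
D Optimized propensity to form reverse turn (synthetic values)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
   -0.6000 -0.2000  1.4000  1.5000 -0.4000  0.1000 -0.3000  1.9000  0.2000 -1.2000
   -1.0000  0.3000 -0.8000 -1.1000  1.7000  1.1000  0.6000 -1.9000 -0.9000 -1.3000
//
H SYNT000101
D Synthetic incomplete hydration scale (W unassigned)
I    A/L     R/K     N/M     D/F     C/P     Q/S     E/T     G/W     H/Y     I/V
    0.3100 -1.0100  0.6000  0.7700  0.1400  0.2200  0.6400  0.0000  0.1300 -1.8100
   -1.7000 -0.9900 -1.2300 -1.4300  0.7200  0.4200  0.3500      NA -1.3100 -1.6200
//
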