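wavelength_nm,V
380,0.0000390
385,0.0000640
390,0.000120
395,0.000217
400,0.000396
405,0.000640
410,0.00121
415,0.00218
420,0.00400
425,0.00730
430,0.0116
435,0.01684
440,0.0230
445,0.0298
450,0.0380
455,0.0480
460,0.0600
465,0.0739
470,0.09098
475,0.1126
480,0.13902
485,0.1693
490,0.20802
495,0.2586
500,0.3230
505,0.4073
510,0.5030
515,0.6082
520,0.7100
525,0.7932
530,0.8620
535,0.91485
540,0.9540
545,0.9803
550,0.99495
555,1.0000
560,0.9950
565,0.9786
570,0.9520
575,0.9154
580,0.8700
585,0.8163
590,0.7570
595,0.6949
600,0.6310
605,0.5668
610,0.5030
615,0.4412
620,0.3810
625,0.3210
630,0.2650
635,0.2170
640,0.1750
645,0.1382
650,0.1070
655,0.0816
660,0.0610
665,0.04458
670,0.0320
675,0.0232
680,0.0170
685,0.01192
690,0.00821
695,0.005723
700,0.004102
705,0.002929
710,0.002091
715,0.001484
720,0.001047
725,0.000740
730,0.000520
735,0.000361
740,0.000249
745,0.000172
750,0.000120
755,0.0000848
760,0.0000600
765,0.0000424
770,0.0000300
775,0.0000212
780,0.0000150
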