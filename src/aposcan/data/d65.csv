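wavelength_nm,power
300,0.03
310,3.3
320,20.2
330,37.1
340,39.9
350,44.9
360,46.6
370,52.1
380,50.0
390,54.6
400,82.8
410,91.5
420,93.4
430,86.7
440,104.9
450,117.0
460,117.8
470,114.9
480,115.9
490,108.8
500,109.4
510,107.8
520,104.8
530,107.7
540,104.4
550,104.0
560,100.0
570,96.3
580,95.8
590,88.7
600,90.0
610,89.6
620,87.7
630,83.3
640,83.7
650,80.0
660,80.2
670,82.3
680,78.3
690,69.7
700,71.6
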