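>SYN0001.1 HIF
A  [  1  17   1   1   1   1   1   1   1   1   1  17   1   1 ]
C  [  1   1  17   1   1   1  17   1   1  17  17   1   1   1 ]
G  [ 17   1   1  17   1  17   1  17  17   1   1   1  17   1 ]
T  [  1   1   1   1  17   1   1   1   1   1   1   1   1  17 ]
>SYN0002.1 NRF1
A  [  1   1   1   1   1  17   1   1   1   1   1  17   1   1 ]
C  [  1   1  17   1  17   1   1   1  17   1  17   1   1   1 ]
G  [  1  17   1  17   1   1  17  17   1  17   1   1   1  17 ]
T  [ 17   1   1   1   1   1   1   1   1   1   1   1  17   1 ]
>SYN0003.1 SP1
A  [  1   1   1   1   1   1   1   1   1   1   1   1  17   1 ]
C  [  1   1   1   1   1  17   1   1   1   1  17  17   1   1 ]
G  [ 17  17  17  17  17   1  17  17  17  17   1   1   1  17 ]
T  [  1   1   1   1   1   1   1   1   1   1   1   1   1   1 ]
>SYN0004.1 ELK1
A  [ 17  17   1   1   1   1  17  17   1   1   1   1   1  17 ]
C  [  1   1  17  17   1   1   1   1   1   1   1  17  17   1 ]
G  [  1   1   1   1  17  17   1   1  17   1  17   1   1   1 ]
T  [  1   1   1   1   1   1   1   1   1  17   1   1   1   1 ]
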