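kit,dnase_units,replicate,alleles_called
GlobalFiler-class,0,1,40
GlobalFiler-class,0,2,40
GlobalFiler-class,0,3,40
GlobalFiler-class,4,1,37
GlobalFiler-class,4,2,37
GlobalFiler-class,4,3,38
GlobalFiler-class,5,1,39
GlobalFiler-class,5,2,35
GlobalFiler-class,5,3,36
GlobalFiler-class,6,1,27
GlobalFiler-class,6,2,25
GlobalFiler-class,6,3,27
Identifiler-class,0,1,28
Identifiler-class,0,2,28
Identifiler-class,0,3,28
Identifiler-class,4,1,28
Identifiler-class,4,2,27
Identifiler-class,4,3,28
Identifiler-class,5,1,28
Identifiler-class,5,2,27
Identifiler-class,5,3,26
Identifiler-class,6,1,21
Identifiler-class,6,2,22
Identifiler-class,6,3,20
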