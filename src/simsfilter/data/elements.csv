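symbol,monoisotopic_mass,dbe_class
H,1.007825032,hydrogen
[2H],2.014101778,hydrogen
C,12.0,carbon
[13C],13.003354838,carbon
N,14.003074005,nitrogen_group
O,15.994914620,neutral
F,18.998403163,halogen
Na,22.989769282,neutral
Al,26.981538530,neutral
P,30.973761998,phosphorus_group
S,31.972071174,neutral
Cl,34.968852682,halogen
[37Cl],36.965902602,halogen
K,38.963706486,neutral
Ca,39.962590863,neutral
Br,78.918337600,halogen
[81Br],80.916289700,halogen
I,126.904471900,halogen
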