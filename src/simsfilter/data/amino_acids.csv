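letter,name,residue_formula
G,glycine,C2H3NO
A,alanine,C3H5NO
S,serine,C3H5NO2
P,proline,C5H7NO
V,valine,C5H9NO
T,threonine,C4H7NO2
C,cysteine,C3H5NOS
L,leucine,C6H11NO
I,isoleucine,C6H11NO
N,asparagine,C4H6N2O2
D,aspartate,C4H5NO3
Q,glutamine,C5H8N2O2
K,lysine,C6H12N2O
E,glutamate,C5H7NO3
M,methionine,C5H9NOS
H,histidine,C6H7N3O
F,phenylalanine,C9H9NO
R,arginine,C6H12N4O
Y,tyrosine,C9H9NO2
W,tryptophan,C11H10N2O
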