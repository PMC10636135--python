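aa,chi1,chi2,chi3,chi4
S,62,,,
S,-177,,,
S,-65,,,
C,62,,,
C,-177,,,
C,-65,,,
T,62,,,
T,-175,,,
T,-65,,,
V,63,,,
V,175,,,
V,-60,,,
I,62,100,,
I,-177,66,,
I,-177,165,,
I,-65,170,,
I,-57,-60,,
L,62,80,,
L,-177,65,,
L,-172,145,,
L,-85,65,,
L,-65,175,,
M,62,180,75,
M,-177,65,180,
M,-177,180,180,
M,-67,180,-75,
M,-65,-65,103,
F,62,90,,
F,-177,80,,
F,-65,-85,,
F,-65,-30,,
Y,62,90,,
Y,-177,80,,
Y,-65,-85,,
Y,-65,-30,,
W,62,-90,,
W,-177,-105,,
W,-177,90,,
W,-65,95,,
W,-65,-5,,
D,62,10,,
D,-177,30,,
D,-70,-15,,
N,62,-10,,
N,-174,-20,,
N,-65,-20,,
N,-65,120,,
H,62,-75,,
H,-177,-165,,
H,-177,60,,
H,-65,-70,,
H,-65,165,,
E,62,180,-10,
E,-177,180,10,
E,-177,65,10,
E,-65,180,-10,
E,-67,-75,-25,
Q,62,180,20,
Q,-177,65,-100,
Q,-177,180,60,
Q,-65,180,-25,
Q,-65,-65,-40,
K,62,180,180,180
K,-177,180,180,180
K,-177,68,180,65
K,-65,180,180,180
K,-65,180,-68,180
K,-90,68,180,180
R,62,180,65,85
R,-177,180,180,85
R,-177,65,65,85
R,-65,180,180,180
R,-65,180,65,85
R,-67,-167,-65,-85
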