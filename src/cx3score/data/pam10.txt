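# PAM10 log-odds (10*log10), Dayhoff chain from MDM78; see scripts/make_pam10.py
     A    R    N    D    C    Q    E    G    H    I    L    K    M    F    P    S    T    W    Y    V
A   10  -15   -9  -10  -15  -10   -8   -7  -22  -12  -16  -23  -10  -18   -7   -5   -5  -27  -17   -8
R  -15   14  -12  -19  -16   -6  -29  -21   -6  -12  -21   -4   -8  -19  -10   -8  -15   -7  -20  -17
N   -9  -12   13   -1  -20   -8   -9   -9   -3  -11  -15   -5  -12  -18  -12   -3   -7  -16  -10  -16
D  -10  -19   -1   13  -23   -9    0   -9  -11  -18  -27  -12  -17  -27  -16  -12  -10  -27  -24  -16
C  -15  -16  -20  -23   15  -26  -26  -19  -15  -13  -37  -29  -21  -31  -16   -9  -16  -27  -10  -13
Q  -10   -6   -8   -9  -26   14   -2  -15   -3  -14  -12   -9   -8  -32   -8  -13  -12  -25  -23  -15
E   -8  -29   -9    0  -26   -2   12  -11  -12  -11  -25  -12  -13  -28  -13  -10  -14  -27  -17  -15
G   -7  -21   -9   -9  -19  -15  -11   10  -19  -25  -24  -17  -15  -18  -14   -7  -14  -28  -28  -13
H  -22   -6   -3  -11  -15   -3  -12  -19   14  -17  -14  -17  -15  -13  -10  -15  -15  -15   -9  -13
I  -12  -12  -11  -18  -13  -14  -11  -25  -17   14   -6  -14   -4   -7  -16  -14   -7  -22  -13   -1
L  -16  -21  -15  -27  -37  -12  -25  -24  -14   -6   10  -29   -2   -9  -15  -19  -16  -14  -16   -8
K  -23   -4   -5  -12  -29   -9  -12  -17  -17  -14  -29   11   -6  -26  -15  -12   -9  -35  -19  -25
M  -10   -8  -12  -17  -21   -8  -13  -15  -15   -4   -2   -6   18   -9  -14  -12   -9  -18  -17   -6
F  -18  -19  -18  -27  -31  -32  -28  -18  -13   -7   -9  -26   -9   14  -19  -14  -19  -11   -2  -22
P   -7  -10  -12  -16  -16   -8  -13  -14  -10  -16  -15  -15  -14  -19   13   -7  -10  -24  -24  -13
S   -5   -8   -3  -12   -9  -13  -10   -7  -15  -14  -19  -12  -12  -14   -7   11   -3  -12  -15  -16
T   -5  -15   -7  -10  -16  -12  -14  -14  -15   -7  -16   -9   -9  -19  -10   -3   12  -23  -14   -8
W  -27   -7  -16  -27  -27  -25  -27  -28  -15  -22  -14  -35  -18  -11  -24  -12  -23   20  -12  -26
Y  -17  -20  -10  -24  -10  -23  -17  -28   -9  -13  -16  -19  -17   -2  -24  -15  -14  -12   15  -16
V   -8  -17  -16  -16  -13  -15  -15  -13  -13   -1   -8  -25   -6  -22  -13  -16   -8  -26  -16   11
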