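# MMFF symbolic atom types and their numeric codes
# columns: symbolic numeric definition
CR       1  ALKYL CARBON
C=C      2  VINYLIC
CGD      2  GUANIDINE CARBON
CSP2     2  GENERIC CSP2
C=N      3  C=N
C=O      3  GENERAL CARBONYL C
C=ON     3  AMIDE CARBONYL
C=OR     3  KETONE OR ALDEHYDE CO
C=OS     3  THIOESTER, C=O
C=P      3  CARBON DOUBLY BONDED TO P
C=S      3  THIOESTER, C=S
C=SN     3  THIOAMIDE
CONN     3  UREA CARBONYL C
COO      3  CARBOXYLIC ACID OF EST
COON     3  CARBAMATE CARBONYL
COOO     3  CARBONIC ACID OR ESTER
CS=O     3  CARBON IN >C=S=O
CSO2     3  CARBON IN >C=SO2
CSS      3  THIOCARBOXYLIC ACID OR ESTER C
=C=      4  ALLENIC C
CSP      4  ACETYLENIC C
HC       5  H-C
HP       5  H-P
HSI      5  H-SI
-O-      6  GENERAL DIVALENT OX
-OP      6  OTHER DIVALENT O ON P
-OS      6  OTHER DIVALENT O ON S
OC=C     6  ENOL OR PHEMOLIC O
OC=N     6  OXYGEN IN -O-C=N MOIETY
OC=O     6  ESTER OR ACID -O-
OC=S     6  THIOESTER -O-
ON=O     6  NITRITE ESTER OXYGEN
ONO2     6  NITRATE ESTER OXYGEN
OPO      6  PAIR OF DIVALENT O ON P
OPO2     6  DIVALENT O IN PHOSPHITE
OPO3     6  DIVALENT O IN PHOSPHATE
OR       6  O-CSP3
OS=O     6  DIVALENT OXYGEN ON S=O
OSO      6  PAIR OF DIVALENT O ON S
OSO2     6  DIVALENT O IN SULFITE
OSO3     6  DIVALENT O IN SULFATE
O=C      7  O=C, GENERIC
O=CN     7  O=C IN AMIDES
O=CO     7  O=C IN ACIDS, ESTERS
O=CR     7  O=C IN KET, ALD
O=CS     7  O=C IN THIOESTERS
O=N      7  NITROSO-GROUP OXYGEN
O=S      7  TERMINAL O SULFOXIDES
O=S=     7  TERMINAL O=S IN SULFINES
NR       8  AMINE N
N=C      9  N=C, IMINES
N=N      9  N=N, AZO COMPOUNDS
NC=O    10  N-C=O, AMIDES
NC=S    10  N-C=S (DELOC LP)
NN=C    10  N-N=C (DELOC LP)
NN=N    10  N-N=N (DELOC LP)
F       11  FLUORINE
CL      12  CHLORINE
BR      13  BROMINE
I       14  IODINE
S       15  THIOL, SULFIDE
S=C     16  S DOUBLY BONDED TO C
>S=N    17  SULFUR DOUBLY BONDED TO N
S=O     17  SULFOXIDE S
=SO2    18  OXYGENATED SULFONE S
SNO     18  NITROGEN ANALOG OF SO2
SO2     18  SULFONE S
SO2N    18  SULFONAMIDE S
SO3     18  SULFONATE S
SO4     18  SULFATE SULFUR
SI      19  SILICON
CR4R    20  C IN CYCLOBUTYL
HO      21  GENERAL H ON O
HOR     21  H-O, ALCOHOLS
CR3R    22  C IN CYCLOPROPLY
H3N     23  H, AMMONIA
HN      23  GENERAL H-N
HNM     23  H ON ANIONIC (DEPROTONATED) N
HNOX    23  H-N IN N-OXIDE
HNR     23  H-N, AMINES
HPYL    23  H-N IN PYRROLE
HOCO    24  H-O, ACIDS
HOP     24  H-O-P, PHOS ACIDS
PO      25  TETRACRD P, 2 OXYGENS
PO2     25  TETRACRD P, 2 OXYGENS
PO3     25  TETRACRD P, 3 OXYGENS
PO4     25  PHOSPHODIESTER
PTET    25  GENERAL TETRACRD P
P       26  TRICOORDINATE P
HN=C    27  IMINE N-H
HN=N    27  AZO N-H
HNCC    28  H-N, ENAMINES
HNCN    28  H-N, HN-C=N
HNCO    28  H-N, AMIDES
HNCS    28  H-N, THIOAMIDES
HNNC    28  H-N, HN-N=C
HNNN    28  H-N, HN-N=N
HSP2    28  GENERAL H ON SP2 N
HOCC    29  H-O, ENOLS, PHENOLS
HOCN    29  H-O IN HO-C=N
CE4R    30  C=C IN 4-RING
HOH     31  H-OH
O-S     32  SINGLE TERM O ON TET S
O2CM    32  O, CARBOXYLATE ANION
O2N     32  NITRO-GROUP OXYGEN
O2NO    32  NITRO-GROUP IN NITRATE
O2P     32  TERMINAL O, O2P GROUP
O2S     32  SULFONES, SULFONAMIDES
O3N     32  NITRATE ANION OXYGEN
O3P     32  TERMINAL O, O3P GROUP
O3S     32  SULFONATES, TERM OX
O4CL    32  TERMINAL O IN CLO4(-)
O4P     32  TERMINAL O, PO4(-3)
O4S     32  SO4(3-)
OP      32  TERMINAL O, O-P
OSMS    32  THIOSULFINATE O (-1/2)
OXN     32  OXIDE ON NITROHGEN
HOS     33  H-O-S, SULF ACIDS
NR+     34  N+, QUATERNARY N
OM      35  OXIDE OXYGEN ON SP3 C
OM2     35  OXIDE OXYGEN ON SP2 C
HGD+    36  H ON GUANIDINIUM N
HIM+    36  H ON IMIDAZOLIUM N
HN5+    36  H ON POSITIVE AROM 5-RING N
HNC+    36  H ON PROTONATED N+=C-N
HNN+    36  H ON IMIDAZOLIUM N
HNR+    36  H-N+
HPD+    36  H ON PYRIDINIUM N
CB      37  AROMATIC C
NPYD    38  AROMATIC N, PYRIDINE
NPYL    39  AROMATIC N, PYRROLE
NC%C    40  N ATTACHED TO TRIPLE-BONDED C
NC=C    40  N-C=C (DELOC LP)
NC=N    40  N-C=N (DELOC LP)
NC=P    40  N-C=P (DELOC LP)
CO2M    41  C IN CO2- ANION
CS2M    41  THIOCARBOXYLATE C
NSP     42  N TRIPLE BONDED
NC%N    43  N ATTACHED TO CYANO GROUP
NPO2    43  N, PHOSPHONAMIDES
NPO3    43  N, PHOSPHATAMIDES
NSO2    43  N, SULFONAMIDES
NSO3    43  SULFONATE N
STHI    44  S IN THIOPHENE
NO2     45  NITRO GROUP N
NO3     45  NITRATE GROUP N
N=O     46  NITROSO GROUP N
NAZT    47  TERMINAL N, AZIDE
NSO     48  DIVAL. N IN S(N)(O) GP
O+      49  OXONIUM (TRICOORD) O
HO+     50  H ON OXONIUM OXYGEN
O=+     51  OXENIUM OXYGEN+
HO=+    52  H ON OXENIUM O+
=N=     53  N TWICE DOUBLE BONDED
N+=C    54  IMINIUM NITROGEN
N+=N    54  AZONIUM NITROGEN
NCN+    55  N IN +N=C-N: ; Q=1/2
NGD+    56  GUANIDINIUM N; Q=1/3
CGD+    57  GUANIDINIUM CARBON
CNN+    57  C IN +N=C-N RESONANCE
NPD+    58  N PYRIDINIUM ION
OFUR    59  AROMATIC O, FURAN
C%      60  ISONITRILE CARBON
NR%     61  ISONITRILE N
NM      62  SULFONAMIDE N-
C5A     63  ALPHA AROM 5-RING C
C5B     64  BETA AROM 5-RING C
N5A     65  ALPHA AROM 5-RING N
N5B     66  ALPHA AROM 5-RING N
N2OX    67  NITROGEN IN N-OXIDE
N3OX    68  NITROGEN IN N-OXIDE
NPOX    69  NITROGEN IN N-OXIDE
OH2     70  OXYGEN IN WATER
HS      71  H-S
HS=N    71  H ON S DOUBLY BONDED TO N
S-P     72  TERMINAL SULFUR ON P
S2CM    72  THIOCARBOXYLATE S
SM      72  TERMINAL SULFUR ON C
SSMO    72  TERM S, THIOSULFINATE
SO2M    73  SULFUR IN SULFINATE
SSOM    73  SULFUR, THIOSULFINATE
=S=O    74  SULFINYL SULFUR, C=S=O
-P=C    75  P DOUBLY BONDED TO C
N5M     76  NEG N IN TETRAZOLE AN
CLO4    77  CHLORINE IN CLO4(-)
C5      78  GENERAL AROM 5-RING C
N5      79  GENERAL AROM 5-RING N
CIM+    80  C IN N-C-N, IM+ ION
N5+     81  POSITIVE GENERAL AROM 5-RING N
N5A+    81  POSITIVE ALPHA AROM 5-RING N
N5B+    81  POSITIVE BETA AROM 5-RING N
NIM+    81  N IN N-C-N, IM+ ION
N5AX    82  5R NITROGEN IN N-OXIDE
N5BX    82  5R NITROGEN IN N-OXIDE
N5OX    82  5R NITROGEN IN N-OXIDE
FE+2    87  IRON +2 CATION
FE+3    88  IRON +3 CATION
F-      89  FLUORIDE ANION
CL-     90  CHLORIDE ANION
BR-     91  BROMIDE ANION
LI+     92  LITHIUM CATION
NA+     93  SODIUM CATION
K+      94  POTASSIUM CATION
ZINC    95  DIPOSITIVE ZINC CATION
ZN+2    95  DIPOSITIVE ZINC CATION
CA+2    96  DIPOSITIVE CALCIUM CATION
CU+1    97  MONOPOSITIVE COPPER CATION
CU+2    98  DIPOSITIVE COPPER CATION
MG+2    99  DIPOSITIVE MAGNESIUM CATION
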