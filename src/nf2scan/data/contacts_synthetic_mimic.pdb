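HEADER    SYNTHETIC CONSTRUCTED COORDINATES              01-JAN-24   XXXX
TITLE     SYNTHETIC MIMIC OF FERM/C-TERM PEPTIDE CONTACT GEOMETRY
REMARK   1 SYNTHETIC FIXTURE; NOT EXPERIMENTAL DATA
ATOM      1    N TYR A 244      -4.690   1.000   0.800  1.00  0.00           N
ATOM      2   CA TYR A 244      -3.790   1.600   0.000  1.00  0.00           C
ATOM      3    C TYR A 244      -4.290   3.000   0.000  1.00  0.00           C
ATOM      4    O TYR A 244      -3.690   4.000   0.300  1.00  0.00           O
ATOM      5   CG TYR A 244      -1.390   0.000   0.000  1.00  0.00           C
ATOM      6  CD1 TYR A 244      -0.695   1.204   0.000  1.00  0.00           C
ATOM      7  CD2 TYR A 244      -0.695  -1.204   0.000  1.00  0.00           C
ATOM      8  CE1 TYR A 244       0.695   1.204   0.000  1.00  0.00           C
ATOM      9  CE2 TYR A 244       0.695  -1.204   0.000  1.00  0.00           C
ATOM     10   CZ TYR A 244       1.390   0.000   0.000  1.00  0.00           C
ATOM     11   OH TYR A 244       2.750   0.000   0.000  1.00  0.00           O
ATOM     12   CB TYR A 244      -2.590   0.900   0.000  1.00  0.00           C
ATOM     13    N PRO A 252       7.990  -0.300   0.800  1.00  0.00           N
ATOM     14   CA PRO A 252       7.890   1.000   0.500  1.00  0.00           C
ATOM     15    C PRO A 252       9.090   1.700   0.100  1.00  0.00           C
ATOM     16    O PRO A 252      10.190   1.200   0.200  1.00  0.00           O
ATOM     17   CG PRO A 252       5.590   0.000   0.000  1.00  0.00           C
ATOM     18   CB PRO A 252       6.590   1.100   0.000  1.00  0.00           C
ATOM     19   CD PRO A 252       6.790  -0.900   0.400  1.00  0.00           C
ATOM     20    N GLU A 260      24.250  -1.800   0.900  1.00  0.00           N
ATOM     21   CA GLU A 260      25.150  -2.300   0.000  1.00  0.00           C
ATOM     22    C GLU A 260      24.550  -3.600  -0.400  1.00  0.00           C
ATOM     23    O GLU A 260      23.450  -4.000  -0.100  1.00  0.00           O
ATOM     24  OE1 GLU A 260      30.000   0.000   0.000  1.00  0.00           O
ATOM     25   CD GLU A 260      28.750   0.000   0.000  1.00  0.00           C
ATOM     26  OE2 GLU A 260      28.150   1.100   0.000  1.00  0.00           O
ATOM     27   CG GLU A 260      27.750  -1.100   0.000  1.00  0.00           C
ATOM     28   CB GLU A 260      26.350  -1.600   0.300  1.00  0.00           C
TER
ATOM     29    N ARG B 588      40.300  -1.100   2.300  1.00  0.00           N
ATOM     30   CA ARG B 588      39.700  -1.500   1.100  1.00  0.00           C
ATOM     31    C ARG B 588      40.700  -2.000   0.100  1.00  0.00           C
ATOM     32    O ARG B 588      41.700  -2.600   0.400  1.00  0.00           O
ATOM     33  NH1 ARG B 588      32.700   0.000   0.000  1.00  0.00           N
ATOM     34   CZ ARG B 588      33.900   0.500   0.000  1.00  0.00           C
ATOM     35  NH2 ARG B 588      34.300   1.750   0.000  1.00  0.00           N
ATOM     36   NE ARG B 588      35.150   0.000   0.200  1.00  0.00           N
ATOM     37   CD ARG B 588      36.500   0.300   0.400  1.00  0.00           C
ATOM     38   CG ARG B 588      37.400  -0.800   0.600  1.00  0.00           C
ATOM     39   CB ARG B 588      38.800  -0.400   0.800  1.00  0.00           C
TER
END
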