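{
 "domains": {
  "A": {
   "anchor_cols": [
    10,
    43,
    61,
    86,
    97,
    100,
    123,
    190,
    191,
    192,
    193,
    194,
    195,
    196,
    197,
    198,
    238,
    263,
    276,
    295,
    310,
    311,
    339,
    359,
    383,
    395,
    398,
    417,
    420,
    421,
    422,
    423,
    424,
    425,
    426,
    427,
    428,
    429,
    430,
    491
   ],
   "motifs": {
    "A3_SGTTGxPK": 190,
    "A8_GRxDxQVKIRG": 420
   },
   "signature10_idx": [
    2,
    3,
    9,
    11,
    13,
    15,
    19,
    20,
    25,
    27
   ],
   "signature34_cols": [
    213,
    217,
    232,
    234,
    241,
    246,
    251,
    256,
    262,
    269,
    273,
    289,
    290,
    291,
    297,
    298,
    300,
    301,
    304,
    308,
    309,
    327,
    329,
    331,
    334,
    335,
    341,
    349,
    352,
    357,
    360,
    374,
    377,
    387
   ],
   "template": "FKPMDKAEHERRKIYTSHQFMEGAKEDHERIKKECLGQIYLKMANQQTKAGNCGLWDRLMNMVELSMQQLIDATRMPYCCFGTAMGPNLVWEESDCYGLITLETHDCTVTPDSRMVIKDHTCGPANAWTCAMCDRQVALAITRLGLTCNCCDFGYEKGDVSTDMEYSAHSFGACLYRADARVMELKQMDISGTTGNPKGFCMRHDPRWYIVEPFWFRKSRPFQNCRDAETYRANTHQSFYYENFNKLIWKMAGPILPKCAQINNERDCHRYMMIRCAMEHVNNRAECGPCCPYRRQRKVRCTSYRWMRQVKYYGYVMLKDMPGIQLCNNAIHPEEPEDTLRQMYDKSVFIKYMQVWVQIHPSGPQWVFCTGDRMSQWEKIRFWRTDSKMPPAMFMPDGQILIFYCRIMPVTNLSQWHDVNGRIDNQVKIRGYWMYASYPRQWLAQLWARIGLEVMHWEPDVPGWLRYSDHDGQYALDGQDEDDIRCLMWPLGTILEIPHR"
  },
  "C": {
   "anchor_cols": [
    50,
    68,
    69,
    90,
    105,
    120,
    130,
    131,
    132,
    133,
    134,
    135,
    136,
    161,
    170,
    224,
    227,
    233,
    236,
    251,
    253,
    261,
    267,
    280,
    304,
    308,
    310,
    316,
    323,
    333,
    359,
    360,
    367,
    384,
    421,
    426,
    430,
    438,
    443,
    447
   ],
   "motifs": {
    "HHxxxDG": 130
   },
   "subtype_cols": [
    24,
    27,
    49,
    51,
    57,
    66,
    88,
    102,
    103,
    113,
    121,
    138,
    142,
    144,
    163,
    184,
    190,
    192,
    215,
    217,
    223,
    225,
    231,
    238,
    254,
    265,
    266,
    290,
    299,
    321,
    334,
    345,
    362,
    386,
    423,
    431,
    436,
    439,
    442,
    444
   ],
   "subtypes": {
    "conventional": "KKNAVWILVDSMQDLMRWWLLVMYWKNFWKMCTFYDTVDF",
    "dual": "ETQTKYLNWSEPRQVACEEVCWPHKIIMRRWPCKCMNEIA",
    "starter": "HITISQGHMHDMPTDDHSSMEFVKKVHTQSTRRIMDWMSY"
   },
   "template": "KTWGRACCLFGCQCTRHVECQTQPLRAWLPTIKWPIHCLLHDCMFATWPHPGWQCIYVEWPKPPCFWVYLTELWTNMDFMMQIYSQRSCMAVRETPHPEELWQCTPWWEFGRMNHCLCTHIPRQKHNACEHHILVDGRSYWMIYCPFRGWGPSGEADESNGQSVHAIVYIAMVMCLNDLKAIAWYRMWWMSHMWPDEYFKRRGYTDIFFMLADSGALREKIWNNQETCTWKIKYYPDDNHYRDYWMNGRNESPAEVSNNMHLRAAGYMKNFCQAWTFMECHLDAHWCYSKNQSVNETVFWQEVEPATWKREFVHDKVVYFKPWDESIVRFVTVGECPAHALYIICGFPKPSNMVLVWRLFLKSFPVKATGMPPGFVMIQANPSVEEGDMWVNIFKSRAQQNDCPTRKHFQNMGIILAPPKNELMWILADYKQQMCWMSVGPKLHMHFALW"
  },
  "T": {
   "anchor_cols": [
    3,
    6,
    21,
    22,
    24,
    29,
    30,
    33,
    35,
    36,
    37,
    38,
    39,
    40,
    41,
    43,
    45,
    51,
    52,
    57,
    59,
    66,
    71,
    79
   ],
   "motifs": {
    "xGGxSx": 35
   },
   "template": "IYQYNTNFMPPAYWQMTDVWMCHCVRLICYYWYFVLGGHSLIKMGHFWWYRHTHHTGRTAQVNTMSPEVIHACGMRHNNA"
  },
  "TE": {
   "anchor_cols": [
    0,
    2,
    6,
    15,
    22,
    35,
    36,
    38,
    39,
    46,
    63,
    64,
    74,
    76,
    80,
    81,
    82,
    83,
    84,
    88,
    90,
    92,
    107,
    119,
    120,
    126,
    130,
    132,
    139,
    150,
    153,
    160,
    170,
    183,
    184,
    198,
    208,
    226,
    238,
    246
   ],
   "motifs": {
    "GxSxG": 80
   },
   "subtype_cols": [
    5,
    8,
    20,
    25,
    29,
    32,
    33,
    40,
    51,
    79,
    91,
    95,
    101,
    102,
    105,
    108,
    122,
    123,
    155,
    174,
    178,
    181,
    185,
    187,
    196,
    202,
    211,
    222,
    227,
    249
   ],
   "subtypes": {
    "TE1": "QMAHGPQKKAITHGIPTDKNPPRDRQLGES",
    "TE2": "GLHQLDAMTQCFRCFPYYDCPGENSPDFFQ"
   },
   "template": "MKIAQIGGNARLAQTMTVQDHWWSPLKILQCMKALVNRRHMPVGTSFFVMNGDAADRGWKNDRGQDANTIADVLPWDIVPGYSQGMFTCSRHSMHPRQVPWYKGDALTEKTHYCTVQVEGGACFWATHLMIVDFVVWKYHWYNWKGLCQLTCAFTLVNKANSMSPLQHDKIIIKAFILYLNYGSLMKFCCSRYHFHNPPMDHVLYETSHYEDTFREAASCFFNTYCVFSDNFNKIPQLEVSGRMWKHELY"
  }
 },
 "scan": {
  "score_threshold": 0.6
 }
}
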