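cohort,group,trait,r,n,ci_low,ci_high
FINNISH_TWINS,MZM,neuroticism,0.43,1998,0.39,0.47
FINNISH_TWINS,DZM,neuroticism,0.20,4862,0.16,0.23
FINNISH_TWINS,MZF,neuroticism,0.48,2226,0.45,0.52
FINNISH_TWINS,DZF,neuroticism,0.19,4658,0.16,0.22
FINNISH_TWINS,MZM,extraversion,0.44,1999,0.40,0.48
FINNISH_TWINS,DZM,extraversion,0.14,4861,0.11,0.17
FINNISH_TWINS,MZF,extraversion,0.52,2227,0.49,0.55
FINNISH_TWINS,DZF,extraversion,0.15,4663,0.12,0.18
MCTFR,MZM,neuroticism,0.53,922,0.47,0.60
MCTFR,DZM,neuroticism,0.17,506,0.05,0.28
MCTFR,MZF,neuroticism,0.45,1054,0.38,0.52
MCTFR,DZF,neuroticism,0.26,580,0.15,0.37
MCTFR,MZM,extraversion,0.52,922,0.45,0.58
MCTFR,DZM,extraversion,0.23,506,0.11,0.34
MCTFR,MZF,extraversion,0.51,1054,0.45,0.57
MCTFR,DZF,extraversion,0.13,580,0.02,0.25
NTR,MZM,neuroticism,0.45,1124,0.40,0.50
NTR,DZM,neuroticism,0.22,855,0.14,0.29
NTR,MZF,neuroticism,0.51,2249,0.47,0.54
NTR,DZF,neuroticism,0.23,1391,0.17,0.28
NTR,DOS,neuroticism,0.21,2044,0.16,0.26
NTR,MZM,extraversion,0.47,1123,0.42,0.52
NTR,DZM,extraversion,0.13,855,0.06,0.21
NTR,MZF,extraversion,0.49,2248,0.46,0.52
NTR,DZF,extraversion,0.20,1392,0.14,0.26
NTR,DOS,extraversion,0.14,2044,0.09,0.19
QIMR_ADOLESCENTS,MZM,neuroticism,0.51,304,0.42,0.59
QIMR_ADOLESCENTS,DZM,neuroticism,0.27,252,0.15,0.38
QIMR_ADOLESCENTS,MZF,neuroticism,0.39,329,0.29,0.48
QIMR_ADOLESCENTS,DZF,neuroticism,0.19,268,0.07,0.30
QIMR_ADOLESCENTS,DOS,neuroticism,0.21,463,0.13,0.30
QIMR_ADOLESCENTS,MZM,extraversion,0.49,304,0.40,0.57
QIMR_ADOLESCENTS,DZM,extraversion,0.18,252,0.06,0.30
QIMR_ADOLESCENTS,MZF,extraversion,0.45,329,0.36,0.53
QIMR_ADOLESCENTS,DZF,extraversion,0.19,268,0.07,0.31
QIMR_ADOLESCENTS,DOS,extraversion,0.12,463,0.03,0.21
QIMR_ADULTS,MZM,neuroticism,0.45,1182,0.40,0.50
QIMR_ADULTS,DZM,neuroticism,0.11,889,0.04,0.19
QIMR_ADULTS,MZF,neuroticism,0.48,2075,0.45,0.52
QIMR_ADULTS,DZF,neuroticism,0.22,1435,0.17,0.28
QIMR_ADULTS,DOS,neuroticism,0.13,1827,0.08,0.18
QIMR_ADULTS,MZM,extraversion,0.48,1182,0.43,0.53
QIMR_ADULTS,DZM,extraversion,0.19,889,0.11,0.26
QIMR_ADULTS,MZF,extraversion,0.48,2075,0.44,0.51
QIMR_ADULTS,DZF,extraversion,0.16,1435,0.11,0.21
QIMR_ADULTS,DOS,extraversion,0.14,1827,0.09,0.19
STR,MZM,neuroticism,0.54,3188,0.51,0.56
STR,DZM,neuroticism,0.18,4841,0.15,0.21
STR,MZF,neuroticism,0.45,2830,0.42,0.49
STR,DZF,neuroticism,0.16,4625,0.13,0.19
STR,MZM,extraversion,0.54,3188,0.51,0.56
STR,DZM,extraversion,0.25,4841,0.22,0.28
STR,MZF,extraversion,0.44,2830,0.41,0.48
STR,DZF,extraversion,0.20,4625,0.17,0.23
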