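sample_set	method	gene	rank	score
all_samples	deltact	18S	1	0.95
all_samples	deltact	EIF4A	2	1.67
all_samples	deltact	TBC	3	1.71
all_samples	deltact	UBQ10	4	1.74
all_samples	deltact	UBC21	5	1.82
all_samples	deltact	HNR	6	1.85
all_samples	deltact	EF1A	7	1.94
all_samples	deltact	EP	8	2.02
all_samples	deltact	PP2A	9	2.05
all_samples	deltact	GAPDH1	10	2.06
all_samples	genorm	HNR	1	0.68
all_samples	genorm	EIF4A	2	0.70
all_samples	genorm	EF1A	3	0.71
all_samples	genorm	PP2A	4	0.78
all_samples	genorm	UBC21	5	0.78
all_samples	genorm	TBC	6	0.83
all_samples	genorm	EP	7	0.92
all_samples	genorm	GAPDH1	8	0.93
all_samples	genorm	UBQ10	9	1.09
all_samples	genorm	18S	10	1.33
all_samples	normfinder	EIF4A	1	0.15
all_samples	normfinder	HNR	2	0.21
all_samples	normfinder	EF1A	3	0.24
all_samples	normfinder	UBC21	4	0.34
all_samples	normfinder	PP2A	5	0.35
all_samples	normfinder	TBC	6	0.38
all_samples	normfinder	GAPDH1	7	0.49
all_samples	normfinder	EP	8	0.51
all_samples	normfinder	UBQ10	9	0.62
all_samples	normfinder	18S	10	0.85
all_samples	bestkeeper	18S	1	0.78
all_samples	bestkeeper	EIF4A	2	1.42
all_samples	bestkeeper	UBQ10	3	1.43
all_samples	bestkeeper	TBC	4	1.51
all_samples	bestkeeper	HNR	5	1.68
all_samples	bestkeeper	GAPDH1	6	1.68
all_samples	bestkeeper	UBC21	7	1.69
all_samples	bestkeeper	EF1A	8	1.74
all_samples	bestkeeper	EP	9	1.80
all_samples	bestkeeper	PP2A	10	1.80
seedlings	deltact	UBC21	1	0.34
seedlings	deltact	GAPDH1	2	0.50
seedlings	deltact	EP	3	0.51
seedlings	deltact	HNR	4	0.56
seedlings	deltact	EF1A	5	0.57
seedlings	deltact	UBQ10	6	0.60
seedlings	deltact	EIF4A	7	0.60
seedlings	deltact	PP2A	8	0.73
seedlings	deltact	18S	9	0.80
seedlings	deltact	TBC	10	0.91
seedlings	genorm	EIF4A	1	0.39
seedlings	genorm	HNR	2	0.42
seedlings	genorm	EP	3	0.44
seedlings	genorm	UBQ10	4	0.45
seedlings	genorm	PP2A	5	0.45
seedlings	genorm	EF1A	6	0.50
seedlings	genorm	UBC21	7	0.51
seedlings	genorm	TBC	8	0.65
seedlings	genorm	18S	9	0.76
seedlings	genorm	GAPDH1	10	0.85
seedlings	normfinder	HNR	1	0.13
seedlings	normfinder	PP2A	2	0.14
seedlings	normfinder	UBC21	3	0.18
seedlings	normfinder	EIF4A	4	0.21
seedlings	normfinder	EP	5	0.29
seedlings	normfinder	UBQ10	6	0.35
seedlings	normfinder	EF1A	7	0.35
seedlings	normfinder	TBC	8	0.40
seedlings	normfinder	GAPDH1	9	0.42
seedlings	normfinder	18S	10	0.63
seedlings	bestkeeper	UBC21	1	0.25
seedlings	bestkeeper	EP	2	0.38
seedlings	bestkeeper	GAPDH1	3	0.44
seedlings	bestkeeper	EF1A	4	0.45
seedlings	bestkeeper	HNR	5	0.48
seedlings	bestkeeper	EIF4A	6	0.55
seedlings	bestkeeper	UBQ10	7	0.57
seedlings	bestkeeper	PP2A	8	0.65
seedlings	bestkeeper	18S	9	0.66
seedlings	bestkeeper	TBC	10	0.85
seeds	deltact	18S	1	1.32
seeds	deltact	TBC	2	2.12
seeds	deltact	EIF4A	3	2.16
seeds	deltact	EP	4	2.23
seeds	deltact	HNR	5	2.26
seeds	deltact	UBC21	6	2.34
seeds	deltact	PP2A	7	2.37
seeds	deltact	EF1A	8	2.39
seeds	deltact	UBQ10	9	2.46
seeds	deltact	GAPDH1	10	2.83
seeds	genorm	EF1A	1	0.56
seeds	genorm	EP	2	0.56
seeds	genorm	HNR	3	0.58
seeds	genorm	PP2A	4	0.61
seeds	genorm	EIF4A	5	0.61
seeds	genorm	UBC21	6	0.71
seeds	genorm	TBC	7	0.83
seeds	genorm	UBQ10	8	0.86
seeds	genorm	GAPDH1	9	0.90
seeds	genorm	18S	10	1.18
seeds	normfinder	EF1A	1	0.11
seeds	normfinder	EP	2	0.12
seeds	normfinder	HNR	3	0.16
seeds	normfinder	PP2A	4	0.19
seeds	normfinder	EIF4A	5	0.22
seeds	normfinder	UBC21	6	0.33
seeds	normfinder	TBC	7	0.46
seeds	normfinder	UBQ10	8	0.48
seeds	normfinder	GAPDH1	9	0.55
seeds	normfinder	18S	10	0.76
seeds	bestkeeper	18S	1	1.19
seeds	bestkeeper	EIF4A	2	1.99
seeds	bestkeeper	TBC	3	2.00
seeds	bestkeeper	EP	4	2.03
seeds	bestkeeper	HNR	5	2.06
seeds	bestkeeper	UBQ10	6	2.13
seeds	bestkeeper	PP2A	7	2.18
seeds	bestkeeper	UBC21	8	2.20
seeds	bestkeeper	EF1A	9	2.24
seeds	bestkeeper	GAPDH1	10	2.45
endosperms	deltact	18S	1	0.54
endosperms	deltact	EIF4A	2	0.87
endosperms	deltact	TBC	3	0.92
endosperms	deltact	UBC21	4	1.08
endosperms	deltact	EP	5	1.13
endosperms	deltact	HNR	6	1.13
endosperms	deltact	UBQ10	7	1.34
endosperms	deltact	PP2A	8	1.36
endosperms	deltact	EF1A	9	1.52
endosperms	deltact	GAPDH1	10	1.63
endosperms	genorm	HNR	1	0.51
endosperms	genorm	PP2A	2	0.52
endosperms	genorm	UBC21	3	0.55
endosperms	genorm	EIF4A	4	0.57
endosperms	genorm	EP	5	0.63
endosperms	genorm	EF1A	6	0.64
endosperms	genorm	UBQ10	7	0.68
endosperms	genorm	GAPDH1	8	0.70
endosperms	genorm	TBC	9	0.72
endosperms	genorm	18S	10	0.98
endosperms	normfinder	EIF4A	1	0.06
endosperms	normfinder	HNR	2	0.06
endosperms	normfinder	UBQ10	3	0.14
endosperms	normfinder	EP	4	0.14
endosperms	normfinder	PP2A	5	0.16
endosperms	normfinder	EF1A	6	0.24
endosperms	normfinder	UBC21	7	0.24
endosperms	normfinder	TBC	8	0.40
endosperms	normfinder	18S	9	0.48
endosperms	normfinder	GAPDH1	10	0.57
endosperms	bestkeeper	18S	1	0.41
endosperms	bestkeeper	EIF4A	2	0.65
endosperms	bestkeeper	TBC	3	0.79
endosperms	bestkeeper	UBC21	4	0.89
endosperms	bestkeeper	HNR	5	0.90
endosperms	bestkeeper	EP	6	1.03
endosperms	bestkeeper	PP2A	7	1.05
endosperms	bestkeeper	EF1A	8	1.18
endosperms	bestkeeper	UBQ10	9	1.20
endosperms	bestkeeper	GAPDH1	10	1.24
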