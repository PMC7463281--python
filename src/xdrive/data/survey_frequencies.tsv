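study	n	freq_SR	freq_BM	freq_T	freq_ST
sturtevant_dobzhansky_1936	416	0.135	0	0	0.865
dobzhansky_1939	1071	0.100	0	0	0.900
koller_1943	175	0.160	0	0	0.840
dobzhansky_1943	224	0.138	0	0	0.862
dobzhansky_1944	10495	0.149	0	0	0.851
dobzhansky_epling_1944	5753	0.096	0	0	0.904
wallace_1948	3866	0.124	0	0.001	0.875
dobzhansky_1947	2214	0.140	0	0	0.860
policansky_dempsey_1978	1561	0.195	0	0	0.805
beckenbach_1996	684	0.193	0.001	0.003	0.803
pooled	26459	0.13455	0.00004	0.00015	0.86526
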