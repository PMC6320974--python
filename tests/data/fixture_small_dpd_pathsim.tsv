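# DPD PathSim of the small fixture, computed by explicit path enumeration
D000	D001	D002	D003	D004	D005	D006	D007	D008	D009	D010	D011
D000	1.0	0.0	0.0	0.5	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
D001	0.0	1.0	0.5	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
D002	0.0	0.5	1.0	0.5	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
D003	0.5	0.0	0.5	1.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
D004	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0
D005	0.0	0.0	0.0	0.0	0.0	1.0	0.5	0.0	0.0	0.0	0.0	0.0
D006	0.0	0.0	0.0	0.0	0.0	0.5	1.0	0.0	0.0	0.0	0.0	0.0
D007	0.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.0	0.0	0.0
D008	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	0.0	0.5	0.5
D009	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	1.0	0.5	0.5
D010	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.5	0.5	1.0	1.0
D011	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.0	0.5	0.5	1.0	1.0
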