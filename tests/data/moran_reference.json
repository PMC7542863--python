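{
 "lattice5_row": -0.148210874048072,
 "lattice640_sem_row": 0.139046814273526,
 "path4_row": 0.4
}
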