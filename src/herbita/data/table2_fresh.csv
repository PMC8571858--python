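specimen_id,species,collection_date,dna_conc_ng_ul,od_260_280,od_260_230,amplified,full_sequence,genbank_accession,source_class,partial_sequence
PI 476287,Phalaris aquatica,2019-06-17,60.7,1.97,2.14,+,+,MN811177.1,fresh,-
PI 476288,Phalaris aquatica,2019-06-17,80.7,1.97,2.06,+,-,,fresh,+
PI 303825,Phalaris aquatica,2019-06-17,59.9,1.96,1.93,+,+,MN811173.1,fresh,-
PI 241065,Phalaris arundinacea,2019-06-17,52.2,1.95,2.13,+,-,,fresh,+
PI 422030,Phalaris arundinacea,2019-06-17,28.5,1.84,1.47,+,+,MN811174.1,fresh,-
PI 578800,Phalaris canariensis,2019-06-17,53.6,1.89,1.99,+,+,MN811183.1,fresh,-
PI 578798,Phalaris canariensis,2019-06-17,57.8,1.97,1.79,+,+,MN811184.1,fresh,-
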