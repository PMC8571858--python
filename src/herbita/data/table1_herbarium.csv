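specimen_id,species,collection_date,dna_conc_ng_ul,od_260_280,od_260_230,amplified,full_sequence,genbank_accession,source_class,partial_sequence
ISC-V-0020926,Phalaris angusta,1936-05-16,15.8,1.94,1.44,+,+,MN811167.1,herbarium,-
ISC-V-0020921,Phalaris angusta,1960-04-16,13.8,2.00,1.50,+,+,MN811165.1,herbarium,-
ISC-V-0020922,Phalaris angusta,1964-06-03,14.5,1.97,1.25,+,+,MN811168.1,herbarium,-
ISC-V-0020920,Phalaris angusta,1970-04-12,29.2,1.98,1.89,+,+,MN811166.1,herbarium,-
ISC-V-0020919,Phalaris angusta,1982-04-03,6.1,2.48,1.27,+,+,MN811169.1,herbarium,-
ISC-V-0021399,Phalaris aquatica,1935-09-08,34.6,1.95,1.79,+,+,MN811171.1,herbarium,-
ISC-V-0020927,Phalaris aquatica,1959-08-31,9.1,2.05,1.13,+,+,MN811170.1,herbarium,-
ISC-V-0021398,Phalaris aquatica,1962-07-08,13.9,1.88,0.81,+,+,MN811172.1,herbarium,-
71166,Phalaris arundinacea,1913-06-30,70.8,2.00,1.82,+,-,,herbarium,+
532148,Phalaris arundinacea,1955-05-28,6.9,1.5,0.54,+,+,MN811175.1,herbarium,-
753216,Phalaris arundinacea,1983-08-27,40.7,1.93,2.42,+,+,MN811176.1,herbarium,-
484712,Phalaris arundinacea,2001-06-26,6.3,2.07,2.59,+,+,MN811200.1,herbarium,-
ISC-V-0021036,Phalaris brachystachys,1959-04-08,10.2,2.12,2.43,+,+,MN811180.1,herbarium,-
ISC-V-0021039,Phalaris brachystachys,1959-04-08,10.5,2.37,1.61,+,+,MN811179.1,herbarium,-
ISC-V-0021035,Phalaris brachystachys,1959-04-08,63.3,1.91,2.41,+,+,MN811178.1,herbarium,-
ISC-V-0021037,Phalaris brachystachys,1962-08-10,7.8,2.21,3.90,+,+,MN811181.1,herbarium,-
ISC-V-0021040,Phalaris californica,1903-05-04,16.2,2.03,2.11,+,-,,herbarium,-
ISC-V-0021044,Phalaris californica,1907-05-24,10.6,1.47,0.66,-,-,,herbarium,-
ISC-V-0021043,Phalaris californica,1908-06-18,19.9,1.86,1.04,+,+,MN811182.1,herbarium,-
ISC-V-0021041,Phalaris californica,1958,10.1,2.16,2.52,-,-,,herbarium,-
ISC-V-0021042,Phalaris californica,ND,8.3,1.78,1.79,-,-,,herbarium,-
71226,Phalaris canariensis,1884-08,26.1,1.91,2.62,+,-,,herbarium,+
71229,Phalaris canariensis,1886-07-29,41.9,1.87,2.39,-,-,,herbarium,-
367474,Phalaris canariensis,1938-07-12,73.1,1.95,2.12,+,+,MN811185.1,herbarium,-
619107,Phalaris canariensis,1969-07,87.7,1.88,2.09,+,-,,herbarium,+
ISC-V-0021097,Phalaris caroliniana,1940-05-30,17.8,2.01,2.07,+,+,MN811188.1,herbarium,-
ISC-V-0021081,Phalaris caroliniana,1964-05-28,2.8,2.53,1.74,+,+,MN811187.1,herbarium,-
ISC-V-0021166,Phalaris caroliniana,1973-04-06,7.8,2.28,2.47,+,-,,herbarium,+
ISC-V-0021080,Phalaris caroliniana,1982-05-03,25.9,1.97,2.17,+,+,MN811186.1,herbarium,-
ISC-V-0021199,Phalaris coerulescens,1958-11-24,23.8,2.05,1.61,+,+,MN811190.1,herbarium,-
ISC-V-0021198,Phalaris coerulescens,1958-12-15,5.0,2.60,1.40,+,-,,herbarium,-
ISC-V-0021204,Phalaris coerulescens,1959-04-08,22.9,2.06,1.93,+,-,,herbarium,-
ISC-V-0021203,Phalaris coerulescens,1959-04-08,6.6,2.19,1.45,+,+,MN811189.1,herbarium,-
ISC-V-0021333,Phalaris lemmonii,1888,6.6,1.61,-4.95,-,-,,herbarium,-
ISC-V-0021334,Phalaris lemmonii,1946-04-18,26.2,2.02,1.89,+,-,,herbarium,-
ISC-V-0021329,Phalaris lemmonii,1955-06-15,42.9,1.79,0.79,+,+,MN811192.1,herbarium,-
ISC-V-0021336,Phalaris lemmonii,1956-05-07,9.0,2.11,0.96,+,+,MN811191.1,herbarium,-
ISC-V-0021328,Phalaris lemmonii,1980-05-23,8.8,1.80,0.63,+,-,,herbarium,-
ISC-V-0021344,Phalaris minor,1882-05,12.6,1.92,0.88,-,-,,herbarium,-
229774,Phalaris minor,1901-04,36.3,1.81,2.07,-,-,,herbarium,-
ISC-V-0021338,Phalaris minor,1918-04-12,17.0,1.80,0.72,-,-,,herbarium,-
ISC-V-0021342,Phalaris minor,1958-11-24,12.7,2.11,1.74,-,-,,herbarium,-
ISC-V-0021341,Phalaris minor,1959-04-08,15.3,2.12,1.70,+,+,MN811193.1,herbarium,-
ISC-V-0021360,Phalaris paradoxa,1914-05-13,19.6,2.03,2.20,+,-,,herbarium,-
ISC-V-0021363,Phalaris paradoxa,1915-06-04,10.9,1.71,0.61,-,-,,herbarium,-
ISC-V-0021361,Phalaris paradoxa,1934-06-02,71.8,1.68,0.75,+,+,MN811195.1,herbarium,-
ISC-V-0021362,Phalaris paradoxa,1940-05-03,3.8,1.90,7.05,-,-,,herbarium,-
ISC-V-0021415,Phalaris paradoxa,1959-04-08,2.5,7.42,0.27,+,+,MN811194.1,herbarium,-
ISC-V-0021377,Phalaris truncata,1958-11-11,19.7,1.88,2.68,+,+,MN811198.1,herbarium,-
ISC-V-0021384,Phalaris truncata,1958-11-24,7.7,2.25,2.03,+,+,MN811199.1,herbarium,-
ISC-V-0021395,Phalaris truncata,1958-12-15,30.5,2.06,1.81,+,+,MN811197.1,herbarium,-
ISC-V-0021373,Phalaris truncata,1958-12-24,2.9,2.66,0.38,+,+,MN811196.1,herbarium,-
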