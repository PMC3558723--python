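entry_id	mhc_class	species	role
1BD2	I	human	survey
1FYT	II	human	survey
1J8H	II	human	survey
1MI5	I	human	survey
1OGA	I	human	survey
1QSE	I	human	survey
1ZGL	II	human	survey
2AK4	I	human	survey
2CKB	I	mouse	survey
2IAM	II	human	survey
2PYF	I	human	survey
2WBJ	II	human	survey
3C5Z	II	mouse	survey
3C6O	II	mouse	survey
3FFC	I	human	survey
3HG1	I	human	survey
3MBE	II	mouse	survey
3PL6	II	human	survey
3RDT	II	mouse	survey
3RGV	I	mouse	survey
3SJV	I	human	survey
3TOE	II	human	survey
1NFD	I	mouse	glycan_reference
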