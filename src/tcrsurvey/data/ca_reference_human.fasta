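>human_ca_reference curated human TCR alpha constant-domain (Ig fold) reference author_start=118
YQLRDSKSSDKSVCLFTDFDSQTNVSQSKDSDVYITDKTVLDMRSMDFKSNSAVAWSNKS
DFACANAFNNSIIPEDTFFPSPESS
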