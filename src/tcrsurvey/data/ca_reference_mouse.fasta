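>mouse_ca_reference curated mouse TCR alpha constant-domain (Ig fold) reference author_start=118
PYIQNPEPAVYQLKDPRSQDSTLCLFTDFDSQINVPKTMESGTFITDKTVLDMKAMDSKS
NGAIAWSNQTSFTCQDIFKETNATYPSSDVP
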