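af9986b9b790117494ce395d4d6fd484f5cc28e996a113a72d3a7bd67ee0847a  cfd_penalties.tsv
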