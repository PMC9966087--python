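229d6c9c164a1a92f85219a3d553d9562f18fbe3a93dbbade079d459f606234c  specimens.tsv
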