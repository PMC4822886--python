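>Primer_ExternalFw
GACATTAACCTATAAAAATAGGC
>Primer_ExternalRv
GCATCTTCCAGGAAATCTC
>Primer_Key
TAATACGACTCACTATAGGG
>Primer_Message
GCTAGTTATTGCTCAGCGG
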