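>bsmbi_adapter_5 5' amplification adapter carrying a BsmBI site (printed primer BsmBI-F)
CAGATGACTCGTCTCGCACC
>bsmbi_adapter_3 3' amplification adapter carrying a BsmBI site (reverse complement of printed primer BsmBI-R)
GTTTGGAGACGAAAGGGCCC
>trcRNA Cas9 single-guide scaffold (trcRNA), 76 nt
GTTTTAGAGCTAGAAATAGCAAGTTAAAATAAGGCTAGTCCGTTATCAACTTGAAAAAGTGGCACCGAGTCGGTGC
>tRNA synthetic 71-nt glycine-tRNA-like spacer sized to the published half-oligo arithmetic
AACAAAGCACCAGTGGTCTAGTGGTAGAATAGTACCCTGCACAGACCCGGGTTCGATTCCCGGCTGGTGCA
>primer_bsmbi_f amplification primer for the slot-1 half-oligo pool, forward
CAGATGACTCGTCTCGCACC
>primer_trc_trna_r amplification primer for the slot-1 half-oligo pool, reverse
CTGGTGCTTTGTTGCACCGA
>primer_trc_trna_f amplification primer for the slot-2 half-oligo pool, forward
CCGAGTCGGTGCAACAAAGC
>primer_bsmbi_r amplification primer for the slot-2 half-oligo pool, reverse
GGGCCCTTTCGTCTCCAAAC
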