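>g_m1
ACGGCAGCGAACGGCAGCGATTTTATACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
CAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
CAGCGAACGG
>g_m2
ACGGCAGCGAACGGCAGCGATTTTATTTTATCGGCAGCGAACGGCAGCGAACGGCAGCGAATTTTATACG
GCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACG
GCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACG
GCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACG
GCAGCGAACGGCAGCGAACG
>g_m3
ACGGCAGCGAACGGCAGCGATTTTATTTTATCGGCAGCGAACGGCAGCGAACGGCAGCGAATTTTATCGG
CAGCGAACGGCAGCGAACGGCAGCGAATTTTATCGGCAGCGAACGGCAGCGAACGGCAGCGAATTTTATA
CGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAA
CGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAA
CGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAA
CGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAA
>g_m4
ACGGCAGCGAACGGCAGCGATTTTATTTTATCGGCAGCGAACGGCAGCGAACGGCAGCGAATTTTATCGG
CAGCGAACGGCAGCGAACGGCAGCGAATTTTATACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAG
CGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAG
CGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAG
CGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAG
>g_mat
ACGGCAGCGAACGGCAGCGATTTTATTTTATACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCG
AACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCG
AACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCG
AACGGCAGCGAACGGCAGCGAACGGCAGCG
>g_emb
ACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGA
ACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGA
ACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGA
>g_b1
ACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGA
ACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGA
ACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGA
>g_b2
ACGGCAGCGAACGGCAGCGATTTTATACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
CAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
CAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
CAGCGAACGG
>g_b3
ACGGCAGCGAACGGCAGCGATTTTATACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
CAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
CAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
CAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
>g_b4
ACGGCAGCGAACGGCAGCGATTTTATTTTATACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCG
AACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCG
AACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCG
AACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCG
AACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCG
>g_b5
ACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGA
ACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGA
ACGGCAGCGA
>g_b6
ACGGCAGCGAACGGCAGCGATTTTATACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
CAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
CAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGGCAGCGAACGG
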