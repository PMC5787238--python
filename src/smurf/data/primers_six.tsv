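# Six 16S rRNA gene primer pairs (region_id, forward 5'->3', reverse 5'->3')
1	TGGCGGACGGGTGAGTAA	CTGCTGCCTCCCGTAGGA
2	TCCTACGGGAGGCAGCAG	TATTACCGCGGCTGCTGG
3	CAGCAGCCGCGGTAATAC	CGCATTTCACCGCTACAC
4	AGGATTAGATACCCTGGT	GAATTAAACCACATGCTC
5	GCACAAGCGGTGGAGCAT	CGCTCGTTGCGGGACTTA
6	AGGAAGGTGGGGATGACG	CCCGGGAACGTATTCACC
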