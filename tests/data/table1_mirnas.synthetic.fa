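>hsa-miR-513a-5p MIMAT0002877 synthetic-standin
AUCACAGGAGAGGCAGAGCAGC
>hsa-miR-450b-3p MIMAT0004910 synthetic-standin
AUGGGAUCAAACAUCAGUUAAG
>hsa-miR-769-3p MIMAT0003887 synthetic-standin
CUGGGAUCGCCCCGGUCUUUUG
>hsa-miR-6089 MIMAT0023714 synthetic-standin
GGAGGCCGGACGUGGAAUGAAG
>hsa-miR-4691-3p MIMAT0019782 synthetic-standin
UCAGCCACUGCGUGGAUCAGAA
>hsa-miR-3189-3p MIMAT0015071 synthetic-standin
ACCUUGGGGGUGCCAUUAAAUU
>hsa-miR-140-3p MIMAT0004597 mature-miRNA
UACCACAGGGUAGAACCACGG
>hsa-miR-3065-3p MIMAT0015378 synthetic-standin
ACAGCACCCCAACUGGAAAUUU
>hsa-miR-3940-3p MIMAT0018356 synthetic-standin
CAGCCCGGUAGCGGCUCAACUA
>hsa-miR-3680-3p MIMAT0018107 synthetic-standin
AUUUGCAUAGCAGUCUUGGCUU
>hsa-miR-5089-5p MIMAT0021081 synthetic-standin
GUGGGAUUUUCGUCAUGUGCAU
>hsa-miR-6504-3p MIMAT0025465 synthetic-standin
GAUUACAGCAGCGGAGGUGAAC
>hsa-miR-6506-5p MIMAT0025468 synthetic-standin
CCUGGGAUUUGUUACAUGGCAG
>hsa-miR-619-5p MIMAT0026622 synthetic-standin
GCUGGGAUCCCCAGCAGGACAA
>hsa-miR-4775 MIMAT0019931 synthetic-standin
UUAAUUUUUAUGAUGGACGCGA
>hsa-miR-4735-5p MIMAT0019860 synthetic-standin
ACUAAUUUUUGUAGAAGGGUGG
>hsa-miR-6514-3p MIMAT0025485 synthetic-standin
GUGCCUGUCCGACACUUCACGA
>hsa-miR-4794 MIMAT0019967 synthetic-standin
UCUGGCUACUAACGGGUAGGCU
>hsa-miR-664a-5p MIMAT0005948 synthetic-standin
GCUGGCUACUGGGUCAUCGAAA
>hsa-miR-1273e MIMAT0018079 synthetic-standin
GUGCUUGAUUGGGCCGCUACAU
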