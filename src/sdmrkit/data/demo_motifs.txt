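# Synthetic demonstration motif count matrices (A C G T per row).
# These are synthetic JASPAR-style stand-ins, NOT licensed TRANSFAC data.
>CTCF_SYN_01
1	18	1	1
1	18	1	1
1	1	18	1
1	18	1	1
1	1	18	1
5	5	5	5
1	1	18	1
1	1	18	1
5	5	5	5
1	1	18	1
1	1	18	1
1	18	1	1
18	1	1	1
1	1	18	1
>CTCF_SYN_02
2	2	2	15
2	2	15	2
2	2	15	2
2	15	2	2
2	15	2	2
15	2	2	2
2	15	2	2
2	15	2	2
15	2	2	2
2	2	15	2
2	2	15	2
2	2	15	2
2	2	15	2
2	2	15	2
2	15	2	2
2	2	15	2
2	15	2	2
2	2	2	15
15	2	2	2
>SP1_SYN_01
1	1	18	1
1	1	18	1
1	1	18	1
1	1	18	1
1	18	1	1
1	1	18	1
1	1	18	1
1	1	18	1
1	1	18	1
>SP1_SYN_02
2	2	16	2
2	2	16	2
2	2	16	2
2	2	16	2
2	16	2	2
2	2	16	2
2	2	16	2
2	2	16	2
2	2	16	2
2	16	2	2
>RFX_SYN_01
1	1	18	1
1	1	1	18
1	1	1	18
1	1	18	1
1	18	1	1
1	18	1	1
18	1	1	1
1	1	1	18
1	1	18	1
1	1	18	1
1	18	1	1
18	1	1	1
18	1	1	1
1	18	1	1
>RFX_SYN_02
2	2	16	2
2	2	2	16
2	2	2	16
9	1	9	1
2	16	2	2
2	16	2	2
16	2	2	2
2	2	2	16
2	2	16	2
2	2	16	2
1	9	1	9
16	2	2	2
16	2	2	2
2	16	2	2
>MECP2_SYN_01
2	14	2	2
2	2	14	2
2	14	2	2
2	2	14	2
2	14	2	2
14	2	2	2
>EBOX_SYN_01
1	18	1	1
18	1	1	1
1	18	1	1
1	1	18	1
1	1	1	18
1	1	18	1
>GATA_SYN_01
9	1	1	9
2	2	15	2
15	2	2	2
2	2	2	15
15	2	2	2
9	1	9	1
>NFKB_SYN_01
2	2	14	2
2	2	14	2
2	2	14	2
14	2	2	2
2	14	2	2
2	2	2	14
2	2	2	14
2	2	2	14
2	14	2	2
2	14	2	2
>SYN_00_TAGT
2	2	2	14
14	2	2	2
2	2	14	2
2	2	2	14
14	2	2	2
2	2	2	14
>SYN_01_ACCC
13	1	1	1
1	13	1	1
1	13	1	1
1	13	1	1
1	1	1	13
1	1	13	1
1	1	1	13
>SYN_02_ACCT
19	1	1	1
1	19	1	1
1	19	1	1
1	1	1	19
19	1	1	1
1	1	1	19
19	1	1	1
1	1	1	19
1	1	1	19
1	1	1	19
>SYN_03_CGCA
1	13	1	1
1	1	13	1
1	13	1	1
13	1	1	1
13	1	1	1
1	1	13	1
13	1	1	1
1	1	13	1
1	13	1	1
1	1	1	13
13	1	1	1
1	1	13	1
>SYN_04_CGGC
1	18	1	1
1	1	18	1
1	1	18	1
1	18	1	1
1	18	1	1
1	1	18	1
>SYN_05_GAGA
2	2	14	2
14	2	2	2
2	2	14	2
14	2	2	2
2	2	2	14
2	14	2	2
2	2	2	14
2	2	2	14
>SYN_06_GACT
2	2	12	2
12	2	2	2
2	12	2	2
2	2	2	12
2	2	2	12
2	2	2	12
12	2	2	2
12	2	2	2
2	2	2	12
2	2	12	2
2	2	12	2
2	2	2	12
>SYN_07_AGGC
15	2	2	2
2	2	15	2
2	2	15	2
2	15	2	2
2	2	15	2
15	2	2	2
2	15	2	2
15	2	2	2
15	2	2	2
>SYN_08_ATAC
13	2	2	2
2	2	2	13
13	2	2	2
2	13	2	2
13	2	2	2
2	2	13	2
2	2	13	2
2	13	2	2
13	2	2	2
2	13	2	2
13	2	2	2
13	2	2	2
>SYN_09_AAGT
16	2	2	2
16	2	2	2
2	2	16	2
2	2	2	16
2	16	2	2
16	2	2	2
2	2	16	2
2	2	16	2
2	16	2	2
>SYN_10_TTGA
1	1	1	16
1	1	1	16
1	1	16	1
16	1	1	1
1	1	1	16
1	1	1	16
16	1	1	1
16	1	1	1
1	1	16	1
1	16	1	1
1	16	1	1
>SYN_11_AGGG
15	1	1	1
1	1	15	1
1	1	15	1
1	1	15	1
1	1	1	15
15	1	1	1
1	15	1	1
1	15	1	1
1	15	1	1
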