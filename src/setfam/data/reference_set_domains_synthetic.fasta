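>CLF family=E(z) species=At synthetic surrogate SET-domain sequence
YWKRENNFNWQIYHMGMYDMDGNIKPREEEEPENGMRAKLTGYMRYLNDYNFKQGYVGCE
QHAWMCEYTHFYHIWGSPHECPRQNGFTNTEIHVCTGYTKIYSWWAWHVMQLFPHERDKM
AVKDQWFWFYISSFMWFSIRTATWV
>SDG711 family=E(z) species=Os synthetic surrogate SET-domain sequence
SPQCFTPCWCCQRKPFHPDCASYFRKKYHYEPYMKKIGEVFNIYGRAIEKLKDNIDVHHG
YSHVCLCDQEDSGMLLERPYTQGEPNTPWRWPSIVNGQNPDPKKWPTFASHSRGAMCKTK
ITFRLHWIEKLYLHR
>SDG8 family=Ash species=At synthetic surrogate SET-domain sequence
AKKVLTWCYMPTNLTKCWKHLCMYTHKFEGKSIAEHLMHAASEAVSNHQDNVEEDMHIIM
PTIAHLYVLAYRWEDIKMGNQFDICRFKQQQMWSKCNYPNHPGLNHICFEPIDTNHCMIG
VGWGESHLTEFGQVC
>SDG725 family=Ash species=Os synthetic surrogate SET-domain sequence
DCQCAPMVEIAWWNMTEIEMITWQQSADTEGDRKVAQPLGMDAGHTHVQSHASPMAMWWH
RDRTACINPETGWGLTENIHSRHFFQQMDISSDLLPRNRQCISWCVVHFAPDYEHNCDCW
FECGCMGWVRYHCREVAWSNQPEW
>ATX1 family=Trx species=At synthetic surrogate SET-domain sequence
PEVITVRCGRGFPDHLRYQVEFAWTEEMNNYKSIWPCNCDSTLRQQIANKINKDMFEKWM
NYQSSTWAFPDPTAMCLRYPDWGHHRFTCRLDSASPQVACKNAAIYAGQTIQTVIYMGFA
SKIYDIWCIQGDLMAIW
>SDG723 family=Trx species=Os synthetic surrogate SET-domain sequence
HLNIEDPYFLNGEYQHFTCQPTNDKYTPTGQNVGQGQDSQTACIGFCTTDSGYQAVPIQI
KIYWNQFCTDPEHTRLHWLFNIGPTPAWCWYIVICMGARDGPQKDSRFVYYAMNWQYVRQ
CCYRMAIEDLGMQIEKAKKVEEGP
>SUVH4 family=Su(var) species=At synthetic surrogate SET-domain sequence
GPFIWDRLILLYPAKNWECCNMKNINDQRYHQAHSAAFKLWQEVIWKDFGITKAYTSNIC
QVPADFNIMFKDWSNFACCGGSAVYHHYDAGAGTKDCWFVFFWGEQNMRATMFELQEPCL
DKWHKVKIQPFALEGAF
>SDG714 family=Su(var) species=Os synthetic surrogate SET-domain sequence
RIHYHRQLYLAQEGKMLQKINLVKVDCYYCQPVKLTYYQVAKHIMRSMHWRVMLAEFCPF
WSPKVFWFMHFYYPDMTQYHFSMNEWHCKICWQCAKTTIQAFKIIETDPYVSHRHAPMLM
MRTILKDNGCSLRFYKQMAK
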