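>TerL1 synthetic reference extein
MHLAPDTNHKLARVKLYPHKGRTRSYRFEFSQAEVYGFMQYCEGSPDFNTNDPCHGNQRWGQPGSGKTCA
KPQKCGGARHVEPDGPKPVTQQNGYEMCLLKHSTEFHVQWCCCYFNPWASQEGIIICQQMIWSRKYIYKD
PVKKLDYTIPVLLDCEANCTYKTGALMKYIILARPIWACYFYKIKVPHCAFMNVFCRMFLSSESHHTKIS
GWLLVGVCGIPEGCHMGQSRMMFSFFHAMFACYHMKYFVPCPTIHQRTPAQSEWCGPFETEGVHIYCHTF
>TerL6 synthetic reference extein
MNPHVYFLHTSDHMWELLKLMCWIKYFIFYAVTDWYHTMVEVDDARNCFKEIETGLVHLCDGHYIWDRQW
FGKMALIYDCEKMTGFQDMNVTFDWEPKSSSLLGKEFFMQFDCKRVTHWVKYLWKADNFVMLMYAQRATC
IMNAEEATFFQDNGKLCSWKDHTMWAAFIEMYFDSLTNWETSEHCNIESKVSFECWVCKNMYCWLERKLR
MCSHSYFYLAQNQIVHKGLNAARWQNETCTFCDCEDKMTFDMGEQRIKDVCYHFVFDMTD
>Pham3880 synthetic reference extein
MVGWEEMPEDFYSYTSPYFKPDNKQQDHGQSYSAIPQTHVIDWNAKNGLTGNKACYCNAPKPLPMWNWMF
SEFRCFKPNQFKSHDDFNTRCILIHWNEDGLCRAKTINLEGFIRQDHFLFWMKFNWSKEDEYNMSEFKYK
AWLIVAFMQEGCQTKHVNFYVKCYVMRPTKQHSYSQDCCRALFQVVTKIIPFHSAPCQDEHFAYYECPRC
EARICNFGEM
>RecB synthetic reference extein
MICNYILSWVPPLRAPTADAHMNVWKVKPARRVTKAFKIWSQVDYQDRYNAEEYWGKTQIWQYGKSAYDQ
PIQHARWNLVFGNSEYSWKYPCEPWYTLFINELEAVNYRAPEKKYIQMNYPDLEVCKSTDFVDDFERVID
TLWNSLWAHHTVRDAVDGILIKELSERFYQNAWLFHMLAISILCCCWQMHGAFMFINQLCFFPHATISDG
QDYSHNYHMMVIVEGQRYFL
>RDF synthetic reference extein
MVPCLKPTSCWILYNQIQGVFMYYLGQHGECVSTDSMCNMIAIDFMSRGEEELCFAHWYELCVPWFEWMV
YVQHVDKWFTGDNHERCLDGHVDWQVTYDYWNQFWWEVLHRRPMFNVKFYKCTRAGPIGYCNCYHNNSNS
GQPCLKRTHIMFLKRYRWDEPVKLKLRLIGCMTSRTDCIW
>TdS synthetic reference extein
MCFQNRWLVILVHQDCVYNGCIYPGLRYVLNAGAWVEVASPRQDDSYTRVAADIHEWFWRQAMPVHTGPA
FCLQNFAWHSAWITSYFGGFQGRFYHLLSVFIRKWWVHYKYSGLVHSLMEHSINCCCRKGHARYSCRGLV
REPVQTVPQANSTAHLPCVHGCPVPPDPTKMCGGHPRMEQVEPFQGVTLWEFFAEWRTFYPAKVKSNKGH
RSAWEVAECWKSKAYGTLWESTMVSAITIITAWAVGNGGH
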