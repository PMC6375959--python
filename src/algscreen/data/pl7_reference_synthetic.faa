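>PL7REF001 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFGSALDHNPLNKAGKMKVDVNAKDLVMTLYMKISAGLEYVKKESALAEPDGANLAAHYMRAY
IHMKTMSLNKGHADKGDHQIMYEKINYDQTTSAMDPMYYTGVAIYSRNTEYTDYFKAGSY
>PL7REF002 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFMSANLANAKNKMGKMKVDRNVKDYVHELRLMPYHGLSTPDKESTLREPGLSPRAEHYFIAY
IMMPTRSNKGGGAADGDHQTMYEKLHYDYTTSAMDPGTYMTTAIYQRNHLYYIYFKAGSY
>PL7REF003 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELRETTSAREHEPLHKARKMKVDVNAKDYVGTLQMMPFYELMYVGLESQLSGPRDRYMPIHYMRAM
DMQPTRLNKMPHADDGDHQPMYTPLLYDQTTSDVTPMTYTTQAIYSRNTLYYDYFKAGSY
>PL7REF004 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFMSALEHNELDDPGIMKVDVNAKGLVMTLRMMPSSGLIYVRKETILREPQGSLLAMRYMRAE
AMEKTRSFIRGHFDEGDHQEVYENGHVRQPTSNMDPDTMTYQAIYSMHTHSYFYFKAGSY
>PL7REF005 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFMDALEHQFLNLAGKIKVRVNAQDGFMTLFFMPSYGLIKVRKESIDREPRHSLLETKYLRAR
RMMKIYSNKSGHADDVDHRIQYEKLHYDQTMLVEDPMTYTTQAIYSRNTLLNDYFKAGSY
>PL7REF006 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREYASHLEHHPHNKTGKMKVDVNAKDTVMTLRMTDSKGLIYFRAPSIRDEPRGSLLQTHYMRAY
DMMKTRDLKKGHADRGPHQPEYRKLHMHMTTSAMDQMTYFTAAIYSRNTLYYDYFKAGSY
>PL7REF007 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFPYALEHNPDEKTGKMNVDVNALDYVMTLRTMPSYGPIYVNHDDIKREKRGSFLGAHYMRMN
DEVKTRVLKKYHADDGPHQIMKELLLEDQTTSAMDAKTYTTQFIYERNTVNYDYFKAGSY
>PL7REF008 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFLSHLIHNPLNKEDKMQIDNNAKDVLQEMQMHFGYGLIFVRKESILRLPRLSQLLTHYKIAY
RGHKTRSLKKFHADDFDLQIMYETMHQDQTTPPMDTMTYTTQAQYSRNQKYYDYFKAGSY
>PL7REF009 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFMKAQEHHSLNTHGYYGLDVNAKVYVMLHRMMPHYHLAPTRKESILREPRGSLSATEYRRAI
DMMDTRSLTFVHRDDGDHQIMYEKYNYDETTPAMDPMDYTVQAIYSRITGYFDYFKAGSY
>PL7REF010 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFMQANEHQRANKEGKMLEDRNHKEYVSTLRMMPSMGGQRVRHESILREDRGSLLATHYVRQY
DMQRTHSLKVGSEDDFEHQIYYEKLHDDDTTSNMDSMQYTAQAIYSRDNLYYFYFKAGSY
>PL7REF011 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREKHSALEYNPLNKAGKMKVRVPLKDYVMTLRMMPGYDLIIMRGEGIYREMRGSLLAYHYMRAY
DGAHESALATGVATHSDHQIMFEKLHYDQVYSIMMPMTYTTQAIYSRNKLRLDYFKAGSY
>PL7REF012 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFMHAAEHNPLYKRGKMKYDRNQKDYVMTSFMNVSYGLIYVTKEAILREPFGVMLATHKMRAY
DMRQTRSLKKIHAETGDHQTMYEPLHYVQTNSAEDMFTNTHQVIYSRNSNQYDYFKAGSY
>PL7REF013 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFMSALEHNPLNFAGHMFVDQNGKDYVMGERMMPHNGEKDDRMESFTRLLRGSLHADHYMRAY
DMRKHRMLKHGSHDMGDHQIMYSKLRYDQTQSAMDMMTYTTQANNERNTLYYFYFKAGSY
>PL7REF014 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREFMSADVTQPLNKAGIQLVTTNAKDYVMRARGSASDGLIYVRKVSILRMPRGTLLATHLMFAY
DEMKTRSLDKGFADDGDLQLMYESLHYDQTDSAMDPMTYTTQAIYSRNTLQYVYFKAGSY
>PL7REF015 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREDMSGIEGNPLNKGGKEEVDVNAVDYVMTLRMPPSYGKLYVRKESANREFRGSLLATHYMRAY
DMFKTRSLKAAHVDDGGHQIMYEEQHVTQQKPAMDRMTYTTYAIYSRNTLIYDYFKAGSY
>PL7REF016 synthetic PL7-like protein (A3/A4 scaffold family)
YARSELREDMSAYEHNPLTLAGKVKVAVNAKKYVATLRMMMSYELIDYRFEQNLFFPRGSLLATHYLRHY
DMMKTGSLKKGHAPIDDHQIMYAKLHEDSTTSPHDPMHYTTVAIYSRNKLNYRYFKAGSY
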