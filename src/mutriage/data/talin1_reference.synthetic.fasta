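>TLN1_synthetic_reference length=2541 synthetic stand-in for human talin-1; wild-type residues of the bundled catalog mutations (and K1530/K1544/C1392) fixed at their true letters
HHSGLFPVERLEKMWTMVIRQVKFLRLYATISCIMPRHDGIGHQRDKKAVYVDYWAYGIP
TIKIDGLKHASPHCNNNRLSVEANACDCMNNSGCMGDDFINKHIDKVMPTDYPCDRMDQP
CPGFCWDIAHIIYQNCSSRMCMFQWESTLHPWVGIATPWKHAYTCKQPRDPQKVGCNKQA
LPQEEFSERHKAMHACILAAIEIKLPWQPFHGLIKLSIIWTDVDRPFPPMGCYQVLNWKA
TNLRFIFAEEYAKGAIKQTFMYPWCMWFNNERYQRKMASQVSPCSPPDMKYTDHIGGQPY
KYDSDVIDRPMRSHARRQQDFEEGSPNIQLGQELYNFETHVLFTEADDKWEVWILPQCDR
LYHQPNYVHHYAYVRGEWQMTLWCFLFIPGEIMQHRVRNVGPHDTFIFNQDDSTCISYME
GKGQISYIQYAELSKYIGKYDNWWYTTCFNTTVAMLMVPSRNLDKLAVTVRLNEHTHTAK
GEYMEHGMSSSPVVNCVHHAAINEDSASVNTWTNSWNPDGEFSCYMGCHRPHKPNMPSHP
RWVEEVHPGWNFVEAKACCEHRFETNMAPCGSMCMAVVLCVEYPFVIKAIGWCWMCQRQN
WQKGESDFRVYKACTKDHILPHWFEWFVFHEPTIGVFVPWFFVVSYLYDFGRCAFKTDFY
QYIWHMIDGIYRDVNMFPRLHVNVTSGHAVDDEDMEAPYELKAERADMLFFKENGYGGKV
AQKALSNLSPPNLAYCFVAHPQWISDPRFVFWMTVKLRQAMAEIYHRMWQTTNFENHSNG
WSVMRKRFSQWHASFYCFEMYKMRQHKAQICTMALSEMKSYCKWNTSVAMHSYSTTKKWG
WGSHPQLQADQQVVAWKMHNDIAPFMQRNSQGASSRVGPIASECIQLTASCKALCQTWPS
INYIDYMCFIHECYCELRNGFDWMSGCNIQENAKLAVMAKYTMVGPKCCGFIEFPWSYSF
FNHHLADMSKMQHMGLTDNVTLCFTICENDARHYMEFWEIKFWRPSMKGGVTLFRDLYRK
RYVIVSGHMKRDDWATGCGSSFYSTMHKTSWDGATHYPAISHNITYWVYVNKCMPIKDNP
CQALFPWIYIYQCEWRHRKAHNLKLWTMQIKRWDKNWNHVNGDTGIGNFSFWWVGLPNQD
REVFIDETMPNPFRDGWTHTTCVYIGYFMRQMQCMVWNQDLAAIAWQSAGEMGVDGMSRK
IPARLMQVLVQFCQRTNIMRYTCNQSDKPYYVTPYYYWWTRNETWACQTKVQTCQCSFHY
FRHEFFFNKSVACRSGRNEKADNIWWNIQGPGFRLYTMGESRILLHIKNLKIRDRRILCG
LLSVHKHASHALQKGSSNTDRPYHKTAHQYVQYNTTYDVWIYMCFQNRRIEYNCMSECRH
EPCFRKVRYNHCKCMCCRTLNRKENCNHIMFHTIIRTRITQWMRVQKWWGIERTQACMAY
WAMWCKTSGHHDHMEYGAWDDMLMLFKWALDAHKGRRQAQRKWHGHIQVHVHHIPKNHNS
PPMFQAETRCYVIGTMAKHFPRGFKDDHVKVPPGAAYKLSFGLKTMDGNSITMPHQLYGC
ISFGMGWRVFFHTFMPTNCFVSWKGADRNFRDHRQHGPGVGMNVLLFLYDQLTKEQYHKY
PVMPREKSFPTVKNRCRRDEWMCMFDYSVPTEEMYCMHVSKMKMDEDFRGEQSKLQCIEY
TNMCMAPMIYYQQQLQYIPEVFEQGLTLRKDSKLMKPYIEQSRAQFGVWSFVWQCLCIFW
ELAVGPKFISQTGTGDWHGACPILEICHPEWEVTSSQIDMITQGPLRMTFIADREEINFK
EHMDKFQYAHNYKKVLVEVKSRDIPQIACRNARLSGGTYFEYRITDLLPTEMSEVFIWFC
NRMKTHMMRLQEHDYITQNIVDNAPEIKEIYHVTAMFNTIIPEIFWNPLDPVTMFSSHYL
EPLFWRYMYSCCSSEDVRGMGCAKYSIYFHNKMFYGDRMIVDRKCLITEWYKYKILCFIP
VMEPTECCTCYDILVHPKWTFEIYYAKGTMEMSVIWPHRRLTRIMPIKCLPDWFGHLVPQ
SNCIFHAPAYVTNRWIPYIVCYIFNNCFVNPGSTSDYVDQSQICEDACVPECDGRRTFCQ
YVNTQPHPFSQCGHMHHRPEQLCFPQRMWWNLAKGDIRRISDCIGKWHYDGNANCLTYTI
WSTDYKAMDACRQVVNILCDHVLVQKALRWWPQVFGPEVNLQCYKTASQHQGCDRQEHRN
IGIFVMASWGVVLYELEDHHKMTGAQGMDSVTHYKLTQMKIEMGRKAQWFLQYPKLCSLT
AWCCWLQMPFKAGSDTAMYKCKCYVYCRGVEVLKYPQDMDSNANNHKGEGLLTQFTCTMS
AGDCSFTLDMDVDDYSCDKGPPRLWDGHDGPQDPPFVKRFMEHRNPINYHEGRYWCSANS
YKTLKEISIGHPEIFGYYKNMYQDHRAFHEQYCVGTWMMPLWSERHKKMNPEDCVYETNT
VSFRLDGGPIFWMQSDAGEMKNERRALGWYLCLYFGAGDLCFQQVFVMLCHAPHPRKALM
ENCCTFTQSTTMQWRDCNMNV
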