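>ATREF01 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRHNEAEPRFNLTVKMGLSDQASTDMWRASIAGWFMEIIL
>ATREF02 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINEAFKELGERVPGGASRQAHTDADKWSITGDAIEYIL
>ATREF03 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRIKEDKKFLVLRVPMGASKQASTDATKASILGTAHCYQC
>ATREF04 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRIPEVFKELGLIVEGLASDYASTFADMASILGAAGEYHT
>ATREF05 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRKNEAFKELGLRVIKGASKRASTDADMASILGDMIVYIL
>ATREF06 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINEYFKENGLKFLGGASKQRPTPNDKASILGCHEESIL
>ATREF07 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINEAFWELGLRVPGDASVQAYTDADSASGYGDAIEEIL
>ATREF08 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINGAEKIVGLCLPGGASNPASWDADKYSILKDAIECMH
>ATREF09 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRWNEPFKEDGLRCPGGASSQARTCADPAIFLGDHIEYIL
>ATREF10 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINQLFKELGLSVPGGASKQATTDAQKNSTLGDAIEYRL
>ATREF11 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINEAFKFLLWSVDGGASKQATTDNIKAEIGGDIIFYIE
>ATREF12 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINEAFKELGLTVPRGASKQAVTDAFKADILGDAIEVIL
>ATREF13 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRIDPAFYCYGPSVPGFASKQAHTHADKASILGHAIEYDH
>ATREF14 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINEAFDPLGCRVPGGASKCASTDPESASNLGDAIEYIL
>ATREF15 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINETFKELGLRVPGGASKQASTPATKASILGDDIEWIS
>ATREF16 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRIWFAFKELGLVVPYHAFKQASTTADKASIIKDAIEYKL
>ATREF17 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINEAFRELGLRVPGNNQSQQWTDANKASILGDAPEYIL
>ATREF18 synthetic clade-labelled reference bHLH domain
RERRRRMKHMNEELSRRINEAGKDLDLRVPEGASKQAAKDWFQASILGDAIGYGL
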