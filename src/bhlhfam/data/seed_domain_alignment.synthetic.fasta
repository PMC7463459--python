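>seed01 synthetic bHLH domain seed alignment row
RERRRRMKHMNEELSRRINEAFKELGLRVPGGASKQASTDADKASILGDAIEYIL
>seed02 synthetic bHLH domain seed alignment row
RERRRRMKHMNEEMARRMNEAFKENGLRVPNGASKQCSTDRDKASILGDYREYIL
>seed03 synthetic bHLH domain seed alignment row
RERRLRWVHINEELSRRINEAFKELMLRVPGFASRAASTDADKASILFDAHEYIL
>seed04 synthetic bHLH domain seed alignment row
RERLRRMKHMTEELSRRANEAFKELGLNVPGSASKQASTDYDWASILGDAIEYIL
>seed05 synthetic bHLH domain seed alignment row
RERRSRMKHMNHEFSRKINEAFKEQGLRVPGGASKQASRDAQKASDNGDAIEVIL
>seed06 synthetic bHLH domain seed alignment row
RERRRRMAHCNEELSRRIWEAFKELGLRVPGGASKQVSTDYDKASILGDAITYIL
>seed07 synthetic bHLH domain seed alignment row
RERRRSMKHMNMELSRRINEAFKEFILRVPGGMSKQASTDADRASILGDAIEYIL
>seed08 synthetic bHLH domain seed alignment row
RERYRRMKHMNEEKSRRINEAFKELGLRIPGAASTQADTDADKASILGDAIRYIL
>seed09 synthetic bHLH domain seed alignment row
RERRRRMKHMFEELTRRINEAFKELGLRAPGGASKQASVDADKAQILGDAIEYIL
>seed10 synthetic bHLH domain seed alignment row
RERRRRMKKMNEELSRRINEAFKELGLRVPGGASYQASTDADCASIRGDAIEYIL
>seed11 synthetic bHLH domain seed alignment row
RERRRRMKHMNEELSSCIHEAQKTLGLRVPGGASKQAFTDADKASILGDAIQYIL
>seed12 synthetic bHLH domain seed alignment row
RERRRRMKHMNEELSRRIIEAFKELGLRVPGGASKQASTDADKAIILGDAILYIY
>seed13 synthetic bHLH domain seed alignment row
RERRRRMKHMNEELSRRILEAFKMLGLRVPGIASKQLSTDADKASILGNAIEYIL
>seed14 synthetic bHLH domain seed alignment row
RERRCRMTHMNEELSFRINEAFKELGLRVPGGASKQASTDADKASILGDAIEYIL
>seed15 synthetic bHLH domain seed alignment row
RERRRRMKGMNEELSMRINEAFKEHGLRVPGGASKQASTDADKASCLGDDIEYIL
>seed16 synthetic bHLH domain seed alignment row
KPRRRRMKHMNEELVRRINEAFKQLGLRAPGGASKQASTDADKASILRDAIEYIL
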