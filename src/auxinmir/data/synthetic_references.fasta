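>SYN_TIR1_REF synthetic TIR1/AFB anchor (planted pocket/AC residues)
MQSCPDQPGWFTRQHIWAYDMNKAHCCHHDTWVQLQCGPTGKWDSFVLFASAWWHRIYEE
YASRRFVIWWYFFCFSETSSGDKCEIPICWNDVKEEEIKGKVQATCDHNDHSLMCEWVVP
CVTMVVYNDRPWWMYLRIANFVYCYGFLKWLPIIPKVHKLLWSYNGDYKDPNARPWAHKL
HYVADTGWPYVRQLWIVGAPNMMTQYLIHILGNARLCNVPCAKRVMQKVKSDWMTDCERC
KACTQYPFGPVKNCLWKSRRRPGANYEAYKNLCELLNVWTQQTHPIMEVIPSCLDMSNTW
TYPAHEVLCSDTRKAPNESNITQTLKHQFYMITKYTSCVTMRKKAVFIGHFRDTTSMERE
SMHYHYIILYEWKPKQKYTWCKINMTANVKCGGSIPFKHDTQCNCPGKWKGKKMGVWIEE
PEDPNTTFHPVRGKTHWSLSGELKCMRRIKRLAKDVYWLCHSAAFSCPVEHYLEPNAMRF
HPLRSNWVRREGMQCRHSIRPNNHLHKMNRGYAMHHYYRNCHKMPSYTKTSSMHDTWEGD
SKTSPFQVREIRTFQADLRYRVLVKTHRTWAGQNHMQCCISHKFTYTGNVNFMQKDWGGI
>SYN_ARF_REF synthetic ARF anchor (planted B3 motif, PB1 K/OPCA)
MSYTERFGVHHVRSLFYCISDSGMDISYNCNILGINGSHVFAHWYEWVLTSLDAKGFQQK
WLLFVCKWICCMVLNTEKYEDHKILQACCSREFAYWWECTFISLNHPHCLCKSQFMQLAS
LMIAHGMVSDGRKHIKVEPFRVVWHENVSKMCNEISLTHERHGKPWENNQGKTFWFSYAF
NNWDHARSMFGNYSMEGFPTTTGHEWFHFPGRYSYWILIYNIKDSDHMEKHLVEVLNNAT
ELFTSSFPWIPDEHWQNTLYPDNMCSSDCKSYTQHDKILAWWNKMVNHAALCSNKKDPSH
MLYNVCFKNYCSDGYLMALHQKQFLDHVPGTEGNHTYGIYYQRRVIGIFPEYWVVPGPMI
RYIRQSLQWIKPDVGYMTTWETQIHMCHLHQNQYSKSMAWLYQLGRWCTHYIKPRFICLF
IFNYHDAESNMTQAERVECSLMAKWLSCFIRFAHRFFQKYECYRVYDDAQNTRFYSYTQV
AMMDSNWHLYMQSRPQWDSWLRRLNICNAIRHQPERQTRCWGQGFLWHQGDAPTWAVGTA
MSQHDCKYNGCMHVIAVAWIIVLCNAIYCKERFCQDMLSVSRRCTDNCYEKAAAYQQKLD
AEADKKDLQTTDYHYWKLAETSTINRDIGDCNIIDHCMKP
>SYN_PB1_REF synthetic PB1 domain anchor (slice of SYN_ARF_REF)
CMHVIAVAWIIVLCNAIYCKERFCQDMLSVSRRCTDNCYEKAAAYQQKLDAEADKKDLQT
TDYHYWKLAETSTINRDIGDCNIIDHCMKP
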