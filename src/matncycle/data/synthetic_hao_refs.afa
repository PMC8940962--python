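>Neuropaea_HAO_synthetic
TDCPFCYHMWFNYKKMIVRCPGEPQRPLIHYECLGSDCQTCQPYKKGPAYLYWYLHFAWS
ETYPCCDVMVLWMMKACKIRGSDNKSRRWVIEMFSERGMQPPTSNPNFHWFKGWTVEDSV
YKCRRVLLKI
>Nmobilis_HAO_synthetic
TDVPFCYHMWFNWKKMIKRCPGEPQRPLIHYECLGSDCVLCQPYKKGPAYCYWYLHFAWS
ETYPCCDVMFLWMMKACKIRGSDNKSRRWVIEMFSERGMQPPTSNPNFHWFKCWHVETSV
YNCRRVRLKI
>Kstuttgartiensis_HAO_synthetic
TGVCWCYHMVTNMRDMIKRCPHELQQNYIHVVCLGSDCQQTQPYKHGQLYCLTGLKIAHS
ETYRCCEVMTLTMMTATKIRKSDNLHPLWVIVSFVERGMLPATSNLRQHEFKGAHVHTSV
YPPRRVLLIC
>Cfecus_eHao_synthetic
LDVERCDHLWFNYRKMGKRPPGCPQTPLIHYECQGSDEQQTQPYDPNPRYCLTGMHFAHS
ETWKTCVVLVIWRSCACKRCWSDSKSGRGTIVLFM----YYADSNHNFHWFKGWHVATSV
RKCRPQLLKC
>Ccurvus_eHao_synthetic
LDVERCDHLWFNYRKMGTRPPGCEQTPLIHYECMGSQESQTQPYDPNPRYCLTGMHFAHS
ETWKTCVVMVIWRFCACKRCWSDSKSGRGTIVLFM----YYANSNHNFHWFKGWHVAYSV
RACRRILLMK
>Cmediatlanticus_eHao_synthetic
LDVERCDHLWFNYRKMGKRPPGCPQTPGIHYECMGSDEQQTQPYDPNPRYCLTGMHFRHS
ETWKTCVVMVIWRFCACKRCWSDSKSGRGTQVLFM----YYANENHNFHWFKGWHVATSV
RKCRRQLLKC
>Nprofundicola_eHao_synthetic
LDVERCDHLWFNYRKMGKRPPGCPQTLLIHYECMMYDEQQTQWYDPNPRYCLTGMHFAHS
ERWKTCVVMVIWRFRACKRCWSDSKSGRGTIVLFM----YYANFNHNFHWFKGWHVATPV
TKCRRRLLKC
>NarLike1_synthetic
LDVEQCVFLWQNYRNHGKPPPWCGQCPSKHYWCYGSQYTLTQPLDPNPRYCLFGMAFAHS
ETWNTCVVMATWRFCACKCCWSDSWSTRGTILLFM----YYNNSAPNFHWFKGWIVETSV
SKCHRPLTKC
>NarLike2_synthetic
WDVEQCVFLWQLYRDHGKPPPGCGQCSSKHYWCYGSDYTLTQPLDPNPRYCLFGMAFAHS
ETWNTCVVMATWRFCACKFCWSDAWATRGTILLQM----YYNNSAPNFHWFKGWIVETSV
RKCHRPLLKC
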