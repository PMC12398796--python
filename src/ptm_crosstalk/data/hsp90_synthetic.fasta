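>HSP90A_SYN synthetic stand-in, isoform alpha (732 aa; study-panel residues placed; NOT the real HSP90AA1 sequence)
MICQFMHKMQMDLQSVYKHACDQTKMVQQQFGRTHCWWEDCHTIQNPWTKTVAARQMAGE
CYLYHDQPSKTAEVLKFVQIPDWCIFVWGFPLFKEYNGYDLFFCDLQMMYPFWTNHIHPF
GHGDLMEDILHEREDSRKHVDEIMEQGFQKQSNVPQGMSPQLPNFLDEKPLQNALKRTYV
TGAQWSFDFATRVCWGEPPNLALDPRRDEYVYKKRSPGTCCCEVHWYMLLSGFSEISISF
GYNKCQQQDTFMFTMNCWDWEMSNYIVESCPRYITMKHSTLGKGWLCQFHKVTSENVGRG
YNCSIMINFPYNVCAALTHCSFPQMEYRVSNPTGQMLATMVLMMYCTHFSNATMYYEGSK
GKAEKKKDSQVKPLMSYKSVGTIMNNYWLRWLWFMCFKSQNNLNHNVDSFGKARCGATMK
YGYYNSAYERGIQMSQRQWNCPSSKNHCAYNCSFWVGRKSSLRNRFESCNPGIACSHRYN
SYPSPIVAYSAFKRFFNTMLVMWVIDWCRWQNTSTADRCSDFFNNIIYAPQYIFFSGRTS
SSHYSMWCYRNWSRCVYVAAAFYWKWIFEYKLQTIYCCNKATRHAHEVAESKATKSGVQA
WVHEMEGGVGHSFGKAGCTEKHRDQKWMINPSWVQMIGQDSWIHIHVFKTYIVPWRLMGH
YMKHKPIPGTDEMRISILHQFSHRISIMKCSWTVEGLPHALQLLNYISHKNSQFVYACLW
PPCCCIQWRFKK
>HSP90B_SYN synthetic stand-in, isoform beta (724 aa; study-panel residues placed; NOT the real HSP90AB1 sequence)
MQMFLQRVYLHAIDCTKMVQQQFGRIRCWWEDCHTIQNPWTKTVAASQMAGECYTFHDQP
SKTACVLKFVQIEDWCIFVWDFPTFKEYNGYDLFFCDLMMMYPFWTAHIHPFGHGDFMED
ILHEREDSGKHVDEIMEQGFQKQSNIPDGMSPQLPNQLKEIPEIQALMCTYVTGIQWSFD
FATRVCWGETPNLGLDPRRQEYVYKKGSPGLCCCEVRWYMLWSGFSEISGSFGYLKCQQQ
DEFMWTINCPDWEMSNYIVESCPRDITCKHSTLGKGWLCQFHKVTVEVSGREYNCSIVIN
FPYNVQAKLTHCSFPQMEYPVSNPPGQKGATMVLMMYCTHRSNATMYYEGVKGKAEKKKD
SQVKPLMSYKSVGTQMNQYWLRWLWFMCFKSQNNLNHNVDSFGKARCGATMNYGYYNSAY
ERGIQMSQRQWNCPHSKFGCAYNCSFWVGRKSSLRNRFSSCSFGIACSHRYWSFPSGIVA
CSAFKRFFNTMLVMWVILKCRWTNTSTADRCSDMFNNIIYAPQYIFFSHRTSSSHYSMWC
YYNRSRCVYRAWAFYWKWIFEYKLQTNYCCNKQTRHAHEVGCSKATKSGVQAWVHEMEGG
VGLSFGKAGCTEKHRDQKWMPCPSYVQMCRQDSWIHIHIFKTYIVPERLMGHYMKHKPIP
GTDEMRISNWHQFSHRISIMKCMWYVEGLPHALQLLNSISHKNSQFVGAILVPPCCCGFW
RFKK
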