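>Tigger
MCEDDAAWQMMATSCIEDMFAYVGGYGRGCRQDGTQSHSYIKPESKWLCTTQHFCFRWTITGWLINNCKHNMPQFTYQFADNDDDERNMKFTQNMNAGEWCPPDQDYDEYRQLEHMSEGARGDPLHTILHTLQSDIQFVKMPTIHEAKHMAFKIDGWIKTNIKSEEQHFFHSGFMIKFVTWQAVLCMREDMHYYCRDHANIRIRWQKFQAYAWIPTMMAPWGDKGPMAIASADSPQRDPQTMRNQWVAQPKYGRMPPTHWDADPTIYVENEQCGFEHLELCSWTQINHADYNFEKGNLCDCNFNSVVTHLADMPTWDMENKNFRQMPPGERTHNGHAPAPGTYCLIKCQYQRSQMFTQRQDPKDVKPLRSGGTYPYHPYNTHNKIMLGSVPIPLGIIPVVVDDYYRRCTCLPCLCILFQYSLCVAVNDYPIMWCYNGQQCMGPSSQYAPVTAKKTKAQGPSVVQEQKSAYWWPPHNMLYG
>Fot
MENDYWQQGRQRDKEERVSAQKHGHWQALCDGDSYAPRCSAYVCHICARYGGSHPCYMSYGYTEIGHQCWLHLVIECWGALSWMTFWSNELQACIECDFPTIRDRRPFWLTDRFIMIGDPELYTGACHCQTHNVRHRQGMGQYSPHYYFAKFDEYEMGGVLCGVAKRKVDCNPACLCNQDCQLANIQAPGSNSMRWECATTCMFMRCWIMDQDYVEMHQDGNSRGFNNKLDDYERYTSFLNNMDFWWDCNNCTQCTCNLPRWQTTMRPFWEIPKGNSKDIVDMNSSTWLPWIGTFFQWYEADNGYSCYQLVDIEMMMIESIWQPIWHDRCALDNVSHQHIISVVFPWNDDITAMHIGNDYRDRSVDHPLVFQQTLVKRQQSIAAVSKELLNMGHTQCCETDLEVLLTHIPSIEPGTYTHGAQKARDTCHWFFPIGKRFQN
>mariner
MADWVCNCRFKCKVMVPMEDDYKRPPGKDYSIQDKYQQTRSDEIRNIRIDESVRFVQQQIICRENAGCPPKCPGPRVGDHVVYLMQLLHMPLTRAFRLHFWDAIDGAQWQVHIVHQWDIEPAPRRSYRVDIWNVPSLDYGMKVWRAQQWDGILIRRAQWCFNEEHFDRATHFHEDCKDTTMKTTMWANNQYMIENLHDDCNRMQMQAKRFMWLGKMGDDWECEVISNRHPTYRKPWRMPKLFYRFQRQYHYIDTDGPYRFKIIQNMPGMNHNISLKLWHYHVHCMSFCLISFKCISCFHKTLHSCAFLKMLPRAQSSVCNSCHQNKQFHERKFTKGYCFTGWHKR
>maT
MWAGMGPWLWIFLDMTGDKVTSPIQLGTACCLTNHFFEMREMYALTSAHKDSHNKAQKLYQTAEQNWQCSEAVQFFWMLGLDYNIDRQQNSHASENKCMQIYPPFHDSNKNGMNGNGAIGCFMDFDCVGQWPTTSWADYNIQEMALMMQQSHSANPFNVRGEWVWRNAHQWRMAFLSNCTNGNFSVANLSDKTSITMSELDPGNYYIVKNWIILAHWDCVKVKDRFFDFWWDQRCWYMTAISTYLKIAPLDEESWCLFRQWWGSDHVHFLECHHYMMYTGWCKAENLHIFPTYTQWGSMRQFFGFDYDRRNWNQNLWKWCAKQTVRCDWFFRQFPNGIMI
>GT
MEPAGTNEYWYMETHGHKAIHMWKLSKTRSMECISPTQYGSLAHDLYSCMGLYDYKGNYIVFGSDVFGQLTYDQINNARNIDRIGEDTMWAFSWSNIELAIPHGAHLPAQWDWMWGNDLGMATSMGYFSFIKRGRLKLNWYDQQWKWIEVKYWGHWMTYGDQMKMKKDYYWSQQTAAYRWAAYAQGQDFMECLYMIDVILDYAGRVNGPIVMPEYLMKFYTQKTHDQGKEICTGLYGWADYYCNTEPNNWSPLPWTTWTNVFKHGMYPQWYRHQQFNLRIVKFCLWGIPGECLNQVSEGMHSVGGDKAVATLGSPWETQCEMEVHGRLSPPFDPQREQTWLAVRGKQQIW
>VS
MSEDHTKYGRWGRVCQPVFMFLCKKYIHLFYYHFGQVEGWTDYIVRCMVLNWCARMIQLCMPPTFQHWNKGLHSPQVWKPARDSDQMLTFLKYLQLSTYIWWMMHGSYERDSHFCRWWAVPMFWHEWESPVGWKFALDLRPLPDKLQYYTCLFWIAPEPTRFAEQVHGHVEVWVGWHGHAKMHAVGGGPVGDYWLPFADLWCKLIYVEPGFLHPEKTVNKTYFNRIQPFIELPDWQRHREKWDKHPHYHALNGFNGCHHACIVIYLIAEWGQVHDTPYDHFKMGSGSRLWCKFHNFKYDCEWRLHNFQDRMMMRIFTSLNWSVYQMWSPMFDCVREFFKFMQREL
>Tc1
MDSHNSNNPRWVLRDVKRMFMDMQHANWVQMDCDGVTLNYVNSWTCVFLRCMKLIPGMMNIIIDERHCSICMIMLNFQTFDGGIHGQQEWVIKLELCLFWCTRPEVVLAYGLAHIDSSGHSKLCKECVVTQSKVTDTWYMEQGNWFKYHLMMYFPCEDVNVIWFGYESNARNDIKKWWKDEMDYDQHWKDIVSWPRFNYILWVPIAVPLIPVCVYVPAYEIASQKCIIGTDWQDFRWNSLWIDFDMAIVYTSIQACKWSKVSYHEGKQTITYPDEQFQPQFVGCEGGHSPSDPDHAGPQQMILCPPNCDIWGKFDWVLYWKTYFSVAIQTNPDIFCVYYR
>IC
MIDGNDIAMGWSAMYGPEEGSVDSSDDYHPNSSKADDFAAPLKGKLNLPKKTYEFNVHENHHDINWMPRHIMSHNTHKIFHLTGLKKYNIARNSPQDNQKVMRHTSYLHAKEYGMMQGMNVCYPDHWHLFSDWFGETSHTKFDSIFLGVWVARYPGMQIQYGRHEERNTVFHEPTCMKTVMHFSHLVMAYAEKGNDMGAVETTYKHGHQQVCYPRSWAHMHEMDTSLEIEPMMWAIMLTRLPNKFYAYMNDATCMKVHIENYGLKLKWYLSWSHHFEDHKEAHWHNQEQGFDHIFAFLAGDRMIHIHADMGEVASWPYFMCQNRCCITECHGMKCYSKAV
>IT
MGKWGPITKGMVSDADHLDISCYRCDYSCSPENIWIPDLIGLIPKNSTNWGRFKLVHECKNAVVNGTEAQMFNNVQRSRCGIKGRKESCWYNINRHAYDVPIGRHTLHLFQPYNKRMENLAPIYDRHACKQTYKRDYMVNWSFGISPWTKRANGPKSLTADKFQIDFWIPYRQEAYITSRAAICKDFAKQRCGETGYDARPRDWWVCVDGWAQDEHYEKFSGLTLNTTCLNAHFIQFDDKDNIRAATHHPEFTWWGHWRNRGRNVYELGRYMVGWEYDNHCIWLDAQPNMYQICWKFWGIQHPTYPKGDIWPVYTRILGIRNMTEFNVFHDVWDKHKPNE
>TR
MTCMMSGATYRCREKTKYRVCMEDEISNSAKHFMCTWHFMKHFSPKYTRIVIATTYPWISTCWHDTHADMYNHPCNVQAMKAQLMIYTYEKHACGKMRKDFPNKPNTFEDYFREKNITGDYWFMGRRACGYGMQNPYMQECKQYFGVITWKEHTQMRLQHCRNDVSPLDWGEPSTKQQNHQTQHYAVTKLRCSEVLNKYKSHTEINDQTFANFCANNFGWATEYRTALVTGSMMHEEQCSHEMENKCKPNADYWHNPMLLYTSDEFTYGKLMLWIVISVPCYKYRFLMRIMVRTAIEEGRRDATMYACKPWFHAHLVCILKEENHYMCLPRLYMEGHLNW
>TRT
MILTATCPGTGEDNYIPLRIDDCWQHYTCEKFVMFRAQLRDCIFNGCTNKKTHQWEDPAFPRMPYNTLWGSDGRIYVCPECTMVFVKMRGEWCGIAFDWRRPLPPASNVLDDWCDENFCSAMRHWSCHNFFTTCTEDVTRHCFMSREDRVFHAENYINVNPYNVNSFLYAMVDVLSWKEDCWLHGGIDFEKITTYLDGLQHHAQHVDPMELAMEYLSIKPRFHDCQEHICNNQKPKVKLDDHLTEFIMMLYFRGMRYTDNIWVWRRAHMCFWYHTHLERDLINEHMLMCVTLRHNDLHTAAMNYDYNYIRELPTMTMHWFTCMVKQTSQATVLSLTGQWR
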