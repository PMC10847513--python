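>P0ADF6 Escherichia_coli EDD
MNPQLLRVTNRIIERSRETRSAYLARIEQAKTSTVHRSQLACGNLAHGFAACQPEDKASL
KSMLRNNIAIITSYNDMLSAHQPYEHYPEIIRKALHEANAVGQVAGGVPAMCDGVTQGQD
GMELSLLSREVIAMSAAVGLSHNMFDGALFLGVCDKIVPGLTMAALSFGHLPAVFVPSGP
MASGLPNKEKVRIRQLYAEGKVDRMALLESEAASYHAPGTCTFYGTANTNQMVVEFMGMQ
LPGSSFVHPDSPLRDALTAAAARQVTRMTGNGNEWMPIGKMIDEKVVVNGIVALLATGGS
TNHTMHLVAMARAAGIQINWDDFSDLSDVVPLMARLYPNGPADINHFQAAGGVPVLVREL
LKAGLLHEDVNTVAGFGLSRYTLEPWLNNGELDWREGAEKSLDSNVIASFEQPFSHHGGT
KVLSGNLGRAVMKTSAVPVENQVIEAPAVVFESQHDVMPAFEAGLLDRDCVVVVRHQGPK
ANGMPELHKLMPPLGVLLDRCFKIALVTDGRLSGASGKVPSAIHVTPEAYDGGLLAKVRD
GDIIRVNGQTGELTLLVDEAELAAREPHIPDLSASRVGTGRELFSALREKLSGAEQGATC
ITF
>P21909 Zymomonas_mobilis EDD
MTDLHSTVEKVTARVIERSRETRKAYLDLIQYEREKGVDRPNLSCSNLAHGFAAMNGDKP
ALRDFNRMNIGVVTSYNDMLSAHEPYYRYPEQMKVFAREVGATVQVAGGVPAMCDGVTQG
QPGMEESLFSRDVIALATSVSLSHGMFEGAALLGICDKIVPGLLMGALRFGHLPTILVPS
GPMTTGIPNKEKIRIRQLYAQGKIGQKELLDMEAACYHAEGTCTFYGTANTNQMVMEVLG
LHMPGSAFVTPGTPLRQALTRAAVHRVAELGWKGDDYRPLGKIIDEKSIVNAIVGLLATG
GSTNHTMHIPAIARAAGVIVNWNDFHDLSEVVPLIARIYPNGPRDINEFQNAGGMAYVIK
ELLSANLLNRDVTTIAKGGIEEYAKAPALNDAGELVWKPAGEPGDDTILRPVSNPFAKDG
GLRLLEGNLGRAMYKASAVDPKFWTIEAPVRVFSDQDDVQKAFKAGELNKDVIVVVRFQG
PRANGMPELHKLTPALGVLQDNGYKVALVTDGRMSGATGKVPVALHVSPEALGGGAIGKL
RDGDIVRISVEEGKLEALVPADEWNARPHAEKPAFRPGTGRELFDIFRQNAAKAEDGAVA
IYAGAGI
>P05791 Escherichia_coli DHAD
MPKYRSATTTHGRNMAGARALWRATGMTDADFGKPIIAVVNSFTQFVPGHVHLRDLGKLV
AEQIEAAGGVAKEFNTIAVDDGIAMGHGGMLYSLPSRELIADSVEYMVNAHCADAMVCIS
NCDKITPGMLMASLRLNIPVIFVSGGPMEAGKTKLSDQIIKLDLVDAMIQGADPKVSDSQ
SDQVERSACPTCGSCSGMFTANSMNCLTEALGLSQPGNGSLLATHADRKQLFLNAGKRIV
ELTKRYYEQNDESALPRNIASKAAFENAMTLDIAMGGSTNTVLHLLAAAQEAEIDFTMSD
IDKLSRKVPQLCKVAPSTQKYHMEDVHRAGGVIGILGELDRAGLLNRDVKNVLGLTLPQT
LEQYDVMLTQDDAVKNMFRAGPAGIRTTQAFSQDCRWDTLDDDRANGCIRSLEHAYSKDG
GLAVLYGNFAENGCIVKTAGVDDSILKFTGPAKVYESQDDAVEAILGGKVVAGDVVVIRY
EGPKGGPGMQEMLYPTSFLKSMGLGKACALITDGRFSGGTSGLSIGHVSPEAASGGSIGL
IEDGDLIAIDIPNRGIQLQVSDAELAARREAQDARGDKAWTPKNRERQVSFALRAYASLA
TSADKGAVRDKSKLGG
>P9WKJ5 Mycobacterium_tuberculosis DHAD
MPQTTDEAASVSTVADIKPRSRDVTDGLEKAAARGMLRAVGMDDEDFAKPQIGVASSWNE
ITPCNLSLDRLANAVKEGVFSAGGYPLEFGTISVSDGISMGHEGMHFSLVSREVIADSVE
VVMQAERLDGSVLLAGCDKSLPGMLMAAARLDLAAVFLYAGSILPGRAKLSDGSERDVTI
IDAFEAVGACSRGLMSRADVDAIERAICPGEGACGGMYTANTMASAAEALGMSLPGSAAP
PATDRRRDGFARRSGQAVVELLRRGITARDILTKEAFENAIAVVMAFGGSTNAVLHLLAI
AHEANVALSLQDFSRIGSGVPHLADVKPFGRHVMSDVDHIGGVPVVMKALLDAGLLHGDC
LTVTGHTMAENLAAITPPDPDGKVLRALANPIHPSGGITILHGSLAPEGAVVKTAGFDSD
VFEGTARVFDGERAALDALEDGTITVGDAVVIRYEGPKGGPGMREMLAITGAIKGAGLGK
DVLLLTDGRFSGGTTGLCVGHIAPEAVDGGPIALLRNGDRIRLDVAGRVLDVLADPAEFA
SRQQDFSPPPPRYTTGVLSKYVKLVSSAAVGAVCG
>P74689 Synechocystis_sp DHAD
MSNNPRSQVITQGTQRSPNRAMLRAVGFGDDDFTKPIVGIANGYSTITPCNMGINDLALR
AEAGLRTAGAMPQLFGTITISDGISMGTEGMKYSLVSREVIADSIETVCNGQRMDGVLAI
GGCDKNMPGAMIAMARLNIPSIFVYGGTIKPGHYAGEDLTVVSAFEAVGQYSAGKIDEET
LYGIERNACPGAGSCGGMFTANTMSSAFEAMGMSLPYSSTMAAVDGEKADSTEESAKVLV
EAIKKQILPSQILTRKAFENAIAVIMAVGGSTNAVLHLLAIANTIGVPLSLDDFETIRHK
VPVLCDLKPSGKYVTTNLHAAGGIPQVMKILLVNGILHGDALTITGQTIAEVLADIPDQP
PAGQDVIHSWDDPVYQEGHLAVLKGNLATEGSVAKISGVKKPVITGPAKVFESEEDCLEA
ILAGKIQAGDVVVVRYEGPKGGPGMREMLAPTSAIIGAGLGDSVGLITDGRFSGGTYGLV
VGHVAPEAYVGGAIALVQEGDQITIDAGKRLLQLNISEEELAQRRAQWTPPQPRYPRGIL
AKYAKLVSSSSLGAVTDIDLF
>P51785 bacterium_sp DHAD
MAELRSNMITQGIDRAPHRSLLRAAGVKEEDFGKPFIAVCNSYIDIVPGHVHLQEFGKIV
KEAIREAGGVPFEFNTIGVDDGIAMGHIGMRYSLPSREIIADSVETVVSAHWFDGMVCIP
NCDKITPGMLMAAMRINIPTIFVSGGPMAAGRTSDGRKISLSSVFEGVGAYQAGKINENE
LQELEQFGCPTCGSCSGMFTANSMNCLSEALGLALPGNGTILATSPERKEFVRKSAAQLM
ETIRKDIKPRDIVTVKAIDNAFALDMALGGSTNTVLHTLALANEAGVEYSLERINEVAER
VPHLAKLAPASDVFIEDLHEAGGVSAALNELSKKEGALHLDALTVTGKTLGETIAGHEVK
DYDVIHPLDQPFTEKGGLAVLFGNLAPDGAIIKTGGVQNGITRHEGPAVVFDSQDEALDG
IINRKVKEGDVVIIRYEGPKGGPGMPEMLAPTSQIVGMGLGPKVALITDGRFSGASRGLS
IGHVSPEAAEGGPLAFVENGDHIIVDIEKRILDVQVPEEEWEKRKANWKGFEPKVKTGYL
ARYSKLVTSANTGGIMKI
>P55186 bacterium_sp2 DHAD
MPPYRSRTTTHGRNMAGARGLWRATGMKDEDFGKPIIAVANSFTQFVPGHVHLKDLGQLV
AREIEAAGGVAKEFNTIAVDDGIAMGHGGMLYSLPSRDLIADSVEYMVNAHCADAIVCIS
NCDKITPGMLMAAMRLNIPVVFVSGGPMEAGKVTVKGKIRALDLVDAMVVAADDSYSDEE
VEAIEKAACPTCGSCSGMFTANSMNCLTEALGLSLPGNGSVLATHADREALFKEAGRVVV
DLCQRWYEQEDATALPRGIATRAAFENAMSLDIAMGGSTNTVLHLLAAAHEGGIDFSMAD
IDRLSRHVPCLSKVAPAKSDVHMEDVHRAGGVMAILGELERGGLIDASQPTVHAPTMGEA
LARWDIGRTNSQIAHEFFKAAPGGKPTQVAFSQAARWEELDLDRENGVIRSVEHPFSKDG
GLAVLFGNLAPEGCIVKTAGVDESILTFRGTARVFESQDAAVSGILGGQVKAGEVVVIRY
EGPKGGPGMQEMLYPTTYLKSKGLGAACALVTDGRFSGGTSGLSIGHVSPEAGEGGLIAL
VETGDPILIDIPTRGITLEVSDAVLAARREAQLARGKDAWTPLNRKRDLTPALRAYAAMT
TNAARGAVRDVSQIERG
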