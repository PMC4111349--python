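id	group	role	library
KF671968	carp_x_notabilis	hybrid	
KF671969	carp_x_notabilis	hybrid	
KF671970	carp_x_notabilis	hybrid	
KF671971	carp_x_notabilis	hybrid	
KF671972	carp_x_notabilis	hybrid	
KF671973	cass_x_notabilis	hybrid	
KF671974	cass_x_notabilis	hybrid	
KF671975	cass_x_notabilis	hybrid	
KF671976	cass_x_notabilis	hybrid	
KF671977	cass_x_notabilis	hybrid	
KF671978	cass_x_notabilis	hybrid	
KF671979	cass_x_notabilis	hybrid	
KF671980	cass_x_notabilis	hybrid	
KF671981	cass_x_notabilis	hybrid	
KF671982	cass_x_notabilis	hybrid	
KF671983	cass_x_notabilis	hybrid	
KF671984	cass_x_notabilis	hybrid	
KF671985	cass_x_notabilis	hybrid	
KF671986	cass_x_notabilis	hybrid	
KF671987	carp_x_notabilis	hybrid	
KF671988	carp_x_notabilis	hybrid	
KF671989	carp_x_notabilis	hybrid	
KF671990	carp_x_notabilis	hybrid	
KF671991	carp_x_notabilis	hybrid	
KF671992	carp_x_notabilis	hybrid	
KF671993	notabilis	paternal	
KF671994	notabilis	paternal	
KF671995	notabilis	paternal	
KF671996	notabilis	paternal	
KF671997	notabilis	paternal	
KF671998	notabilis	paternal	
KF671999	notabilis	paternal	
KF672000	notabilis	paternal	
KF672001	notabilis	paternal	
KF672002	variabilis	hybrid	
KF672003	variabilis	hybrid	
KF672004	variabilis	hybrid	
KF672005	variabilis	hybrid	
KF672006	variabilis	hybrid	
KF672007	variabilis	hybrid	
KF672008	variabilis	hybrid	
KF672009	variabilis	hybrid	
KF672010	variabilis	hybrid	
KF672011	variabilis	hybrid	
KF672012	variabilis	hybrid	
KF672013	variabilis	hybrid	
KF672014	variabilis	hybrid	
KF672015	variabilis	hybrid	
KF672016	variabilis	hybrid	
KF672017	variabilis	hybrid	
KF672018	variabilis	hybrid	
KF672019	carpaticola	maternal	
KF672020	carpaticola	maternal	
KF672021	carpaticola	maternal	
KF672022	carpaticola	maternal	
KF672023	carpaticola	maternal	
KF672024	carpaticola	maternal	
KF672025	carpaticola	maternal	
KF672026	cassubicifolius	maternal	
KF672027	cassubicifolius	maternal	
KF672028	cassubicifolius	maternal	
KF672029	cassubicifolius	maternal	
KF672030	cassubicifolius	maternal	
KF672031	cassubicifolius	maternal	
KF672032	cassubicifolius	maternal	
KF672033	cassubicifolius	maternal	
KF672034	cassubicifolius	maternal	
KF672035	cassubicifolius	maternal	
KF672036	cassubicifolius	clone	S
KF672037	cassubicifolius	clone	S
KF672038	cassubicifolius	clone	S
KF672039	cassubicifolius	clone	S
KF672040	cassubicifolius	clone	S
KF672041	cassubicifolius	clone	S
KF672042	cassubicifolius	clone	S
KF672043	cassubicifolius	clone	S
KF672044	cassubicifolius	clone	S
KF672045	cassubicifolius	clone	S
KF672046	cassubicifolius	clone	S
KF672047	cassubicifolius	clone	S
KF672048	cassubicifolius	clone	S
KF672049	cassubicifolius	clone	S
KF672050	cassubicifolius	clone	S
KF672051	cassubicifolius	clone	S
KF672052	cassubicifolius	clone	S
KF672053	cassubicifolius	clone	S
KF672054	cassubicifolius	clone	S
KF672055	cassubicifolius	clone	S
KF672056	cass_x_notabilis	clone	X
KF672057	cass_x_notabilis	clone	X
KF672058	cass_x_notabilis	clone	X
KF672059	cass_x_notabilis	clone	X
KF672060	cass_x_notabilis	clone	X
KF672061	cass_x_notabilis	clone	X
KF672062	cass_x_notabilis	clone	X
KF672063	cass_x_notabilis	clone	X
KF672064	cass_x_notabilis	clone	X
KF672065	cass_x_notabilis	clone	X
KF672066	cass_x_notabilis	clone	X
KF672067	cass_x_notabilis	clone	X
KF672068	cass_x_notabilis	clone	X
KF672069	cass_x_notabilis	clone	X
KF672070	cass_x_notabilis	clone	X
KF672071	cass_x_notabilis	clone	X
KF672072	cass_x_notabilis	clone	X
KF672073	cass_x_notabilis	clone	X
KF672074	cass_x_notabilis	clone	X
KF672075	cass_x_notabilis	clone	X
KF672076	notabilis	clone	N
KF672077	notabilis	clone	N
KF672078	notabilis	clone	N
KF672079	notabilis	clone	N
KF672080	notabilis	clone	N
KF672081	notabilis	clone	N
KF672082	notabilis	clone	N
KF672083	notabilis	clone	N
KF672084	notabilis	clone	N
KF672085	notabilis	clone	N
KF672086	notabilis	clone	N
KF672087	notabilis	clone	N
KF672088	notabilis	clone	N
KF672089	notabilis	clone	N
KF672090	notabilis	clone	N
KF672091	notabilis	clone	N
KF672092	notabilis	clone	N
KF672093	notabilis	clone	N
KF672094	notabilis	clone	N
KF672095	notabilis	clone	N
KF672096	variabilis	clone	V
KF672097	variabilis	clone	V
KF672098	variabilis	clone	V
KF672099	variabilis	clone	V
KF672100	variabilis	clone	V
KF672101	variabilis	clone	V
KF672102	variabilis	clone	V
KF672103	variabilis	clone	V
KF672104	variabilis	clone	V
KF672105	variabilis	clone	V
KF672106	variabilis	clone	V
KF672107	variabilis	clone	V
KF672108	variabilis	clone	V
KF672109	variabilis	clone	V
KF672110	variabilis	clone	V
KF672111	variabilis	clone	V
KF672112	variabilis	clone	V
KF672113	variabilis	clone	V
KF672114	variabilis	clone	V
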