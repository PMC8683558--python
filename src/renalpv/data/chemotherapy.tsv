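# Default cytotoxic chemotherapy dictionary: variant <TAB> canonical <TAB> class.
# Common cytotoxics with frequent US brand names; user-overridable (pass your own
# file to builtin_ici_vocabulary / load_drug_vocabulary to use a study-specific list).
cisplatin	cisplatin	chemotherapy
platinol	cisplatin	chemotherapy
carboplatin	carboplatin	chemotherapy
paraplatin	carboplatin	chemotherapy
oxaliplatin	oxaliplatin	chemotherapy
eloxatin	oxaliplatin	chemotherapy
paclitaxel	paclitaxel	chemotherapy
taxol	paclitaxel	chemotherapy
nab-paclitaxel	nab-paclitaxel	chemotherapy
abraxane	nab-paclitaxel	chemotherapy
docetaxel	docetaxel	chemotherapy
taxotere	docetaxel	chemotherapy
gemcitabine	gemcitabine	chemotherapy
gemzar	gemcitabine	chemotherapy
pemetrexed	pemetrexed	chemotherapy
alimta	pemetrexed	chemotherapy
cyclophosphamide	cyclophosphamide	chemotherapy
cytoxan	cyclophosphamide	chemotherapy
ifosfamide	ifosfamide	chemotherapy
doxorubicin	doxorubicin	chemotherapy
adriamycin	doxorubicin	chemotherapy
epirubicin	epirubicin	chemotherapy
etoposide	etoposide	chemotherapy
irinotecan	irinotecan	chemotherapy
camptosar	irinotecan	chemotherapy
topotecan	topotecan	chemotherapy
vinorelbine	vinorelbine	chemotherapy
navelbine	vinorelbine	chemotherapy
vincristine	vincristine	chemotherapy
vinblastine	vinblastine	chemotherapy
fluorouracil	fluorouracil	chemotherapy
5-fluorouracil	fluorouracil	chemotherapy
5-fu	fluorouracil	chemotherapy
capecitabine	capecitabine	chemotherapy
xeloda	capecitabine	chemotherapy
methotrexate	methotrexate	chemotherapy
cytarabine	cytarabine	chemotherapy
bleomycin	bleomycin	chemotherapy
mitomycin	mitomycin	chemotherapy
temozolomide	temozolomide	chemotherapy
temodar	temozolomide	chemotherapy
dacarbazine	dacarbazine	chemotherapy
fludarabine	fludarabine	chemotherapy
bendamustine	bendamustine	chemotherapy
carmustine	carmustine	chemotherapy
busulfan	busulfan	chemotherapy
melphalan	melphalan	chemotherapy
chlorambucil	chlorambucil	chemotherapy
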