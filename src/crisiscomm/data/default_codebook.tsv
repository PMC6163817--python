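theme	subcategory	definition	keywords
Risk Messages	Disease mechanisms	Statements on disease mechanisms	Aedes, mosquito-borne
Risk Messages	Symptoms	Statements on symptoms associated with the disease	symptom, mild, febrile, fever, rash*, *pain*, *ache*, conjunctivitis, microcephaly, redeye*, unwell
Warnings	Risk factors	Statements with risk factors or risk groups	pregnan*, travel*, sex, construction sites, mosquito bites, breeding, stagnant water
Warnings	Danger	Statements that highlight the risk of local spread	risk, threat, concern*
Preparations	Responders	Organizations or persons responsible for the emergency	NEA, MOH, The Ministry of Health, National Environment Agency
Preparations	Recommendations	Requests and advice on taking actions for prevention	advise, urge, please, recommend, precaution, take step, take action
Uncertainty Reduction	Case report	Reports and updates of case numbers and clusters	case, cluster
Uncertainty Reduction	Local locality	Statements on local geographic information	Aljunied Crescent, Sims Drive, Kallang Way, Paya Lebar Way, Bedok North, Joo Seng, Bishan, Woodland, Elite Terrace, Joo Avenue, Harvey Cresent, Siglap, Tagore, Ubi Cresent, Jalan Raya, Circuit Road, Sembawang Drive, Kranji Road, Senoko South Road, Lor 101 Changi, Toh Guan Road East, Joo Chiat Place, Watten Estate, Casa Perla, Hillcrest Arcadia, The Arcadia and Watten Hill, Geylang, area
Uncertainty Reduction	Information resources	Websites or infographics for learning more	http, www., read, For more, health advisory, refer to, FAQ*, information, update*
Efficacy	Personal prevention measures	Specific prevention actions one can take	repellent, screen*, condom, mozzie wipeout, mosquito nets, medical attention, prevent…by, protect…by, simple steps, we can, you can
Efficacy	Common responsibility	Expression of common responsibility of the public	let's, let us, all of us, each of us, everyone, all Singaporeans, work together, residents, we all
Reassurance	Calming	Statements that remove uncertainty or fears	we will, we have, has/have been, NEA has, MOH has, MOH will, NEA will, NEA is, MOH is
Reassurance	Thanking and regards	Expression of thanks, approval and regards	well done, thank*
Reassurance	Government interventions	Government intervention responses	measure*, vector control, fog*, surveillance
Dengue	Dengue	Mention of dengue	dengue
Dengue	Wolbachia	Mention of Wolbachia	Wolbachia
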