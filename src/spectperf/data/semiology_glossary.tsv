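code	description	category
SENSA	strange sensation throughout the body	aura
SMELL	strange smell	aura
SLPY	sleepy	aura
BLUR	blurred mind	aura
SITT	sitting down	automatism
STAR	staring	consciousness
INCS	incoherent speech	language
LOAR	looking around	automatism
OA	oral automatisms	automatism
ADEG	automatism, deglutition	automatism
ALAR	alarm	other
HV	hyperventilation	autonomic
ABSI	automatisms, ipsilateral upper limb	automatism
ABU	automatism, bimanual	automatism
CONSCI	impaired consciousness	consciousness
TEUL	tonic extension, upper limbs	motor
IHED	ipsilateral head and eye deviation	motor
WNUC	automatism, contralateral wiping/touching the nose	automatism
ICIM	ictal immobility	consciousness
SPEAR	speech arrest	language
WNUI	automatism, ipsilateral wiping/touching the nose	automatism
ANOM	nominal afasia	language
FEAR	fear	aura
WAKE	awakening	other
TEIUL	tonic extension, ipsilateral upper limb	motor
VOCA	vocalization	language
CVL	cephalic version to the left	motor
DUC	dystonia, contralateral hand	motor
DIZZ	dizziness	aura
LIGHT	see a light	aura
LUMIN	luminous sparkles	aura
BLUV	blurred vision	aura
BUZZ	ear buzzing	aura
THC	tonic contraction of the contralateral half face	motor
HMOV	hyperkinesis	motor
TSUI	tremor, ipsilateral upper limb	motor
TIFI	tremor, ipsilateral lower limb	motor
SMIL	smiling	automatism
ABSC	automatisms, contralateral upper limb	automatism
EMSC	elevation of the contralateral upper limb	motor
CHED	contralateral head and eye deviation	motor
S4IU	sign of 4 with ipsilateral arm extension	motor
EBLB	bilateral eye blinking	motor
GTCC	bilateral tonic-clonic	motor
AGLO	automatism, global	automatism
STARC	contralateral staring	consciousness
CULP	contralateral upper limb paresthesia	aura
CLCU	clonus, contralateral upper limb	motor
EDVT	eye deviation to the top	motor
CLIU	clonus, ipsilateral upper limb	motor
BEC	bilateral eyelid clonus	motor
DCUP	dystonia, contralateral upper limb	motor
YAWN	yawn	automatism
SCRE	screaming	language
DISC	disconnection	consciousness
TF4	tonic flexion 4 limbs	motor
SEND	end of seizure	other
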