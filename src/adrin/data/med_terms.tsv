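metoprolol	medication	0.6
simvastatine	medication	0.6
amlodipine	medication	0.6
atenolol	medication	0.6
lisinopril	medication	0.6
acenocoumarol	medication	0.6
betablokker	medication	0.6
statine	medication	0.6
antistolling	medication	0.6
bisoprolol	medication	0.6
pravastatine	medication	0.6
atorvastatine	medication	0.6
rosuvastatine	medication	0.6
crestor	medication	0.6
nifedipine	medication	0.6
enalapril	medication	0.6
barnidipine	medication	0.6
diltiazem	medication	0.6
verapamil	medication	0.6
fenprocoumon	medication	0.6
furosemide	medication	0.6
bumetanide	medication	0.6
spironolacton	medication	0.6
perindopril	medication	0.6
losartan	medication	0.6
valsartan	medication	0.6
digoxine	medication	0.6
clopidogrel	medication	0.6
ascal	medication	0.6
carbasalaatcalcium	medication	0.6
ezetimibe	medication	0.6
hydrochloorthiazide	medication	0.6
isosorbidemononitraat	medication	0.6
nitroglycerine	medication	0.6
sotalol	medication	0.6
flecainide	medication	0.6
amiodaron	medication	0.6
dipyridamol	medication	0.6
ramipril	medication	0.6
candesartan	medication	0.6
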