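# Default cluster fixture for the synthetic corpus generator.
# First member of each cluster is the canonical form; the rest are
# misspellings, brand names or synonyms that should embed close to it.
- cluster_id: metoprolol
  role: medication
  members: [metoprolol, metroprolol, metopralol, selokeen]
- cluster_id: simvastatine
  role: medication
  members: [simvastatine, simvastine, zocor]
- cluster_id: amlodipine
  role: medication
  members: [amlodipine, amlodipin, norvasc]
- cluster_id: atenolol
  role: medication
  members: [atenolol, atenolool]
- cluster_id: lisinopril
  role: medication
  members: [lisinopril, lisinoprill]
- cluster_id: acenocoumarol
  role: medication
  members: [acenocoumarol, acenocumarol, sintrom]
- cluster_id: duizelig
  role: adr
  members: [duizelig, duizellig, draaierig]
- cluster_id: misselijk
  role: adr
  members: [misselijk, miselijk, misselijkheid]
- cluster_id: hoesten
  role: adr
  members: [hoesten, hoessten, kriebelhoest]
- cluster_id: oedeem
  role: adr
  members: [oedeem, odeem, enkeloedeem]
- cluster_id: hoofdpijn
  role: adr
  members: [hoofdpijn, hoofdpin, migraine]
- cluster_id: moeheid
  role: adr
  members: [moeheid, moeiheid, vermoeidheid]
- cluster_id: dose_change
  role: non_adr_keyword
  members: [verhoogd, verlaagd, opgehoogd, verdubbeld, afgebouwd, gehalveerd]
- cluster_id: demo_red
  role: demo
  members: [rood]
- cluster_id: demo_colors
  role: demo
  members: [blauw, groen, geel, paars]
- cluster_id: demo_symptoms
  role: demo
  members: [jeukend, gezwollen, geirriteerd, schilferend, branderig, vlekkerig]
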