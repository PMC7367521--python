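# Search-string lexicon for the four monitored opioids.
# A plausible stand-in keyword list: canonical names, product names, slang
# and common misspellings. Terms are lowercase; multi-word terms are matched
# as token sequences.
version: 1
drugs:
  fentanyl:
    canonical: [fentanyl]
    products: [duragesic, actiq, fentora, sublimaze, subsys]
    slang: [fent, fenty, china white, apache]
    misspellings: [fentanil, fentynal, fentenyl, fentanyll]
  hydrocodone:
    canonical: [hydrocodone]
    products: [vicodin, norco, lortab, zohydro, vicoprofen]
    slang: [hydro, hydros, vikes, vics]
    misspellings: [hydrocodon, hidrocodone, hydrocodne]
  oxycodone:
    canonical: [oxycodone]
    products: [oxycontin, percocet, roxicodone, percodan]
    slang: [oxy, oxys, roxy, roxies, percs]
    misspellings: [oxycodon, oxicodone, oxycodome]
  oxymorphone:
    canonical: [oxymorphone]
    products: [opana, numorphan]
    slang: [stop signs, octagons]
    misspellings: [oxymorphon, oximorphone, oxymorophone]
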