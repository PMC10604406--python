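# Default deep-SSI keyword lexicon (Swedish clinical notes, English
# canonical names for reporting).  Variants stand in for lemmatized /
# inflected surface forms; multi-word variants match as contiguous token
# sequences after tokenization.  Nonspecific keywords carry a proximity
# requirement: a body-location anchor must occur within five tokens.
language: sv
locations: &locations
  - incision
  - operation wound
  - abdomen
  - wound
  - pelvis
  - duodenum
  - flank
  - gall bladder
  - skin
  - intra abdominal
  - anastomosis
  - colon
  - liver
  - pancreas
  - stomach
  - operation area
  - presacral
  - rectum
  - retroperitoneal
  - intestine
  - small intestine
  - diaphragm
  - midline incision
  - midline wound
  - sutures
  - stitches
  - staples
  # Swedish surface forms
  - buk
  - buken
  - sår
  - såret
  - operationssår
  - operationssåret
  - bäcken
  - hud
  - huden
  - tarm
  - tarmen
  - tunntarm
  - tunntarmen
  - rektum
  - lever
  - pankreas
  - magen
  - anastomos
  - anastomosen
  - diafragma
  - suturer
  - agraffer
entries:
  - canonical_keyword: abscess
    variants: [abscess, abscesses, abscessen, abscesser, abscessbildning]
  - canonical_keyword: anastomotic leakage
    variants:
      - anastomotic leakage
      - anastomosis leakage
      - anastomosläckage
      - anastomosinsufficiens
  - canonical_keyword: drainage
    variants: [drainage, drän, dränage, dränaget, pigtail]
  - canonical_keyword: drained
    variants: [drained, dränerad, dränerat, dräneras, dränerades]
  - canonical_keyword: leakage
    variants: [leakage, läckage, läcka, läckaget]
    requires_proximity: true
    location_terms: *locations
  - canonical_keyword: antibiotics
    variants: [antibiotic, antibiotics, antibiotika, antibiotikabehandling]
  - canonical_keyword: subfebrile
    variants: [subfebrile, subfebril, subfebrilitet]
  - canonical_keyword: fluid
    variants: [fluid, vätska, vätskeansamling, vätskan]
    requires_proximity: true
    location_terms: *locations
  - canonical_keyword: intestinal content
    variants:
      - intestinal content
      - tarminnehåll
  - canonical_keyword: serous
    variants: [serous, serös, seröst]
    requires_proximity: true
    location_terms: *locations
  - canonical_keyword: echo
    variants: [echo, eko, ekogent]
    requires_proximity: true
    location_terms: *locations
  - canonical_keyword: infection
    variants:
      - infection
      - infections
      - infektion
      - infektionen
      - infektionstecken
      - infekterad
      - infekterat
  # Antibiotic substances, incl. common brand names
  - canonical_keyword: piperacillin-tazobactam
    variants:
      - piperacillin tazobactam
      - piperacillin
      - tazobactam
      - tazocin
    is_antibiotic_name: true
  - canonical_keyword: meropenem
    variants: [meropenem, meronem]
    is_antibiotic_name: true
  - canonical_keyword: imipenem
    variants: [imipenem, tienam]
    is_antibiotic_name: true
  - canonical_keyword: metronidazole
    variants: [metronidazole, metronidazol, flagyl]
    is_antibiotic_name: true
  - canonical_keyword: ciprofloxacin
    variants: [ciprofloxacin, ciproxin]
    is_antibiotic_name: true
  - canonical_keyword: cefotaxime
    variants: [cefotaxime, cefotaxim, claforan]
    is_antibiotic_name: true
  - canonical_keyword: trimethoprim-sulfa
    variants:
      - trimethoprim sulfa
      - trimetoprim sulfa
      - trimetoprim
      - bactrim
      - eusaprim
    is_antibiotic_name: true
  - canonical_keyword: cefuroxime
    variants: [cefuroxime, cefuroxim, zinacef]
    is_antibiotic_name: true
  - canonical_keyword: amoxicillin
    variants: [amoxicillin, amimox, amoxicillinum]
    is_antibiotic_name: true
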