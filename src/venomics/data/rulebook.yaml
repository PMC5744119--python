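# Ordered classification rulebook: the first rule whose keywords all occur
# (case-insensitively) in the transcript's annotation text wins.
# family/subtype codes follow the systematic nomenclature (see triage module).
# Edit freely: order encodes precedence, so put specific rules before
# generic ones (e.g. "scorpine" before any bare "potassium" rule).
rules:
  # enzymes
  - {keywords: [phospholipase a2], family: Enz, subtype: PA2}
  - {keywords: [phospholipase b], family: Enz, subtype: PLB}
  - {keywords: [phospholipase d], family: Enz, subtype: PLD}
  - {keywords: [hyaluronidase], family: Enz, subtype: Hya}
  - {keywords: [metalloprote], family: Enz, subtype: MtP}
  - {keywords: [serine protease inhibitor], family: PIn, subtype: Srp}
  - {keywords: [serine protease], family: Enz, subtype: SeP}
  # protease inhibitors (delta-KTx is Kunitz-fold but a channel blocker: first)
  - {keywords: [delta, potassium], family: KTx, subtype: Del}
  - {keywords: [serpin], family: PIn, subtype: Srp}
  - {keywords: [kunitz], family: PIn, subtype: Kun}
  # potassium-channel toxins
  - {keywords: [scorpine], family: KTx, subtype: Scr}
  - {keywords: [alpha, potassium], family: KTx, subtype: Alp}
  - {keywords: [beta, potassium], family: KTx, subtype: Bet}
  - {keywords: [kappa, potassium], family: KTx, subtype: Kap}
  # sodium-channel toxins
  - {keywords: [alpha, sodium], family: NaT, subtype: Alp}
  - {keywords: [beta, sodium], family: NaT, subtype: Bet}
  # calcium-channel toxins
  - {keywords: [calcin], family: CaT, subtype: Clc}
  - {keywords: [liotoxin], family: CaT, subtype: Lio}
  - {keywords: [omegascorpin], family: CaT, subtype: Ome}
  - {keywords: [agatoxin], family: CaT, subtype: Ome}
  # host defense peptides
  - {keywords: [defensin], family: HDP, subtype: Def}
  - {keywords: [ndbp-1], family: HDP, subtype: ND1}
  - {keywords: [ndbp-2], family: HDP, subtype: ND2}
  - {keywords: [ndbp-3], family: HDP, subtype: ND3}
  - {keywords: [ndbp-4], family: HDP, subtype: ND4}
  - {keywords: [ndbp-5], family: HDP, subtype: ND5}
  - {keywords: [anionic], family: HDP, subtype: Ani}
  - {keywords: [waprin], family: HDP, subtype: Wap}
  # other venom components
  - {keywords: [la1], family: Oth, subtype: La1}
  - {keywords: [svwc], family: Oth, subtype: La1}
  - {keywords: [von willebrand factor type c], family: Oth, subtype: La1}
  - {keywords: [crisp], family: Oth, subtype: CRI}
  - {keywords: [cysteine-rich secretory], family: Oth, subtype: CRI}
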