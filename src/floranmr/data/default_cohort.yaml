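# Synthetic 33-sample / 23-species flower cohort (fixture).
#
# This roster is a synthetic reconstruction: it reproduces the sampling
# structure of a multi-species flower survey (33 samples, 23 species,
# color variants for Rosa chinensis, Chrysanthemum x morifolium and
# Calendula officinalis, variety replicates for Brassica oleracea and
# Viola x wittrockiana) with species chosen from taxa commonly traded as
# edible-flower ingredients.  Concentration profiles are not measured
# values; they are drawn lognormally per species from the profile seed
# below (see floranmr.cohort).
cv: 0.1
extraction: methanol
profiles:
  mode: auto
  seed: 101
  sigma: 1.0
samples:
  - {id: rosa-chinensis-pink, species: Rosa chinensis, variant: pink}
  - {id: rosa-chinensis-spotted, species: Rosa chinensis, variant: white-spotted}
  - {id: rosa-chinensis-red, species: Rosa chinensis, variant: red}
  - {id: chrys-morifolium-white, species: Chrysanthemum x morifolium, variant: white}
  - {id: chrys-morifolium-yellow-1, species: Chrysanthemum x morifolium, variant: yellow}
  - {id: chrys-morifolium-yellow-2, species: Chrysanthemum x morifolium, variant: yellow}
  - {id: chrys-morifolium-yellow-orange, species: Chrysanthemum x morifolium, variant: yellow-orange}
  - {id: calendula-orange, species: Calendula officinalis, variant: orange}
  - {id: calendula-yellow, species: Calendula officinalis, variant: yellow}
  - {id: calendula-orange-yellow, species: Calendula officinalis, variant: orange-yellow}
  - {id: brassica-italica, species: Brassica oleracea, variant: var. italica}
  - {id: brassica-capitata, species: Brassica oleracea, variant: var. capitata}
  - {id: brassica-botrytis, species: Brassica oleracea, variant: var. botrytis}
  - {id: viola-purple, species: Viola x wittrockiana, variant: purple}
  - {id: viola-yellow, species: Viola x wittrockiana, variant: yellow}
  - {id: chenopodium-album, species: Chenopodium album}
  - {id: amaranthus-hypochondriacus, species: Amaranthus hypochondriacus}
  - {id: hibiscus-sabdariffa, species: Hibiscus sabdariffa}
  - {id: sphaeranthus-indicus, species: Sphaeranthus indicus}
  - {id: tagetes-patula, species: Tagetes patula}
  - {id: borago-officinalis, species: Borago officinalis}
  - {id: camellia-japonica, species: Camellia japonica}
  - {id: centaurea-cyanus, species: Centaurea cyanus}
  - {id: rosa-hybrida, species: Rosa hybrida}
  - {id: dianthus-caryophyllus, species: Dianthus caryophyllus}
  - {id: monarda-didyma, species: Monarda didyma}
  - {id: petunia-hybrida, species: Petunia x hybrida}
  - {id: catharanthus-roseus, species: Catharanthus roseus}
  - {id: hemerocallis-fulva, species: Hemerocallis fulva}
  - {id: robinia-pseudoacacia, species: Robinia pseudoacacia}
  - {id: sinapis-alba, species: Sinapis alba}
  - {id: sambucus-nigra, species: Sambucus nigra}
  - {id: tropaeolum-majus, species: Tropaeolum majus}
variant_edits:
  # Rosa chinensis colors: flavonoid amplitude up in red, one aromatic
  # resonance absent in the white-spotted flower.
  "Rosa chinensis::red":
    - {action: scale, metabolite: Kaempferol, factor: 2.5}
  "Rosa chinensis::white-spotted":
    - {action: delete, metabolite: Kaempferol, center: 6.44}
  # Chrysanthemum colors: amino/aliphatic differences (white) and an
  # extra flavonoid/anthocyanin aromatic cluster (yellow-orange).
  "Chrysanthemum x morifolium::white":
    - {action: scale, metabolite: Glutamine, factor: 1.8}
    - {action: scale, metabolite: Alanine, factor: 0.4}
  "Chrysanthemum x morifolium::yellow-orange":
    - action: add
      factor: 0.8
      resonance: {center: 6.70, multiplicity: m, rel_intensity: 2.0, assignment: flavonoid aromatic CH}
  # Calendula colors: carbohydrate peak raised and an alkene signal
  # present in the yellow-containing variants; an aromatic aldehyde
  # signal only in the orange flower.
  "Calendula officinalis::yellow":
    - {action: scale, metabolite: Sucrose, factor: 1.8}
    - action: add
      factor: 1.0
      resonance: {center: 5.65, multiplicity: d, j_values: [6.1], rel_intensity: 1.0, assignment: alkene CH}
  "Calendula officinalis::orange-yellow":
    - {action: scale, metabolite: Sucrose, factor: 1.8}
    - action: add
      factor: 1.0
      resonance: {center: 5.65, multiplicity: d, j_values: [6.1], rel_intensity: 1.0, assignment: alkene CH}
  "Calendula officinalis::orange":
    - action: add
      factor: 0.6
      resonance: {center: 9.65, multiplicity: s, rel_intensity: 1.0, assignment: aromatic aldehyde CH}
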