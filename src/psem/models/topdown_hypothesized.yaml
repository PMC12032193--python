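# A-priori top-down model: predators regulate prey and each other;
# landscape covariates act on the carnivores.  Reconstructed from the
# study's narrative description of its hypothesized top-down pathways.
name: topdown_hypothesized
endogenous: [lynx, wolf, fox, wildcat, hare, red_deer, roe_deer, wild_boar]
exogenous: [elevation, tri, forest, road_density]
paths:
  # apex predators -> prey (predation pressure)
  - {cause: wolf, effect: wild_boar, sign: negative, note: primary wolf prey in the Carpathians}
  - {cause: wolf, effect: red_deer, sign: negative, note: secondary wolf prey}
  - {cause: wolf, effect: roe_deer, sign: negative, note: secondary wolf prey}
  - {cause: lynx, effect: roe_deer, sign: negative, note: primary lynx prey}
  - {cause: lynx, effect: hare, sign: negative, note: secondary lynx prey}
  # mesocarnivores -> prey and each other
  - {cause: wildcat, effect: hare, sign: negative, note: wildcat preys on hare}
  - {cause: fox, effect: hare, sign: negative, note: fox preys on hare}
  - {cause: fox, effect: wildcat, sign: negative, note: interference from the larger mesocarnivore}
  # apex predators -> mesocarnivores (carcass subsidy)
  - {cause: wolf, effect: fox, sign: positive, note: scavenging on wolf kills}
  - {cause: lynx, effect: fox, sign: positive, note: scavenging on lynx kills}
  - {cause: lynx, effect: wildcat, sign: positive, note: scavenging on lynx kills}
  # landscape -> carnivores (prior occupancy work in the system)
  - {cause: tri, effect: lynx, sign: negative, note: rugged terrain limits winter movement}
  - {cause: forest, effect: lynx, sign: negative, note: hunts along habitat edges}
  - {cause: road_density, effect: wolf, sign: negative, note: road avoidance}
  - {cause: elevation, effect: wolf, sign: positive, note: remote high ground}
  - {cause: tri, effect: wolf, sign: negative, note: ruggedness limits travel}
  - {cause: forest, effect: wolf, sign: positive, note: forest cover}
  - {cause: elevation, effect: fox, sign: negative, note: prefers lowlands}
  - {cause: forest, effect: fox, sign: positive, note: forest cover}
  - {cause: elevation, effect: wildcat, sign: negative, note: snow-limited at height}
  - {cause: forest, effect: wildcat, sign: positive, note: forest specialist}
correlated_errors: []
whitelist:
  - {cause: wolf, effect: wildcat, sign: positive, note: possible carcass subsidy}
  - {cause: lynx, effect: red_deer, sign: negative, note: occasional predation on calves}
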