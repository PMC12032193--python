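# A-priori bottom-up model: prey availability drives predators, and
# landscape covariates drive the prey base.  Reconstructed from the
# study's narrative description of its hypothesized bottom-up pathways.
name: bottomup_hypothesized
endogenous: [lynx, wolf, fox, wildcat, hare, red_deer, roe_deer, wild_boar]
exogenous: [elevation, tri, forest, road_density]
paths:
  # prey -> predators
  - {cause: wild_boar, effect: wolf, sign: positive, note: primary wolf prey}
  - {cause: red_deer, effect: wolf, sign: positive, note: secondary wolf prey}
  - {cause: roe_deer, effect: wolf, sign: positive, note: secondary wolf prey}
  - {cause: roe_deer, effect: lynx, sign: positive, note: primary lynx prey}
  - {cause: hare, effect: lynx, sign: positive, note: secondary lynx prey}
  - {cause: hare, effect: wildcat, sign: positive, note: wildcat diet}
  - {cause: hare, effect: fox, sign: positive, note: fox diet}
  # landscape -> ungulates
  - {cause: tri, effect: red_deer, sign: negative, note: environmental harshness}
  - {cause: tri, effect: roe_deer, sign: negative, note: environmental harshness}
  - {cause: tri, effect: wild_boar, sign: negative, note: environmental harshness}
  - {cause: elevation, effect: red_deer, sign: negative, note: winter range at low elevation}
  - {cause: elevation, effect: roe_deer, sign: negative, note: less snow at low elevation}
  - {cause: elevation, effect: wild_boar, sign: negative, note: less snow at low elevation}
  - {cause: forest, effect: red_deer, sign: positive, note: forest supports ungulates}
  - {cause: forest, effect: roe_deer, sign: positive, note: forest supports ungulates}
  - {cause: forest, effect: wild_boar, sign: positive, note: forest supports ungulates}
  - {cause: road_density, effect: red_deer, sign: negative, note: road avoidance}
  - {cause: road_density, effect: wild_boar, sign: negative, note: road avoidance}
  - {cause: road_density, effect: roe_deer, sign: positive, note: low-traffic roads may benefit roe deer}
  # landscape -> hare
  - {cause: road_density, effect: hare, sign: negative, note: prefers unfragmented open areas}
  - {cause: forest, effect: hare, sign: negative, note: open-habitat species}
correlated_errors: []
whitelist:
  - {cause: hare, effect: wolf, sign: positive, note: occasional small prey}
  - {cause: red_deer, effect: lynx, sign: positive, note: occasional predation on calves}
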