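# Final combined model: the retained paths of the optimized top-down and
# bottom-up models, as published in the study's coefficient table.
name: combined_final
endogenous: [lynx, wolf, fox, wildcat, hare, red_deer, roe_deer, wild_boar]
exogenous: [elevation, tri, forest, road_density]
paths:
  # lynx
  - {cause: tri, effect: lynx, sign: negative}
  - {cause: hare, effect: lynx, sign: positive}
  - {cause: forest, effect: lynx, sign: negative}
  # wolf
  - {cause: road_density, effect: wolf, sign: negative}
  - {cause: elevation, effect: wolf, sign: positive}
  - {cause: tri, effect: wolf, sign: negative}
  - {cause: wild_boar, effect: wolf, sign: positive}
  - {cause: forest, effect: wolf, sign: positive}
  - {cause: roe_deer, effect: wolf, sign: positive}
  # fox
  - {cause: elevation, effect: fox, sign: negative}
  - {cause: wolf, effect: fox, sign: positive}
  - {cause: lynx, effect: fox, sign: positive}
  - {cause: forest, effect: fox, sign: positive}
  - {cause: hare, effect: fox, sign: positive}
  # wildcat
  - {cause: elevation, effect: wildcat, sign: negative}
  - {cause: forest, effect: wildcat, sign: positive}
  - {cause: lynx, effect: wildcat, sign: positive}
  # hare
  - {cause: tri, effect: hare, sign: negative}
  - {cause: elevation, effect: hare, sign: positive}
  - {cause: forest, effect: hare, sign: negative}
  # red deer
  - {cause: road_density, effect: red_deer, sign: negative}
  - {cause: forest, effect: red_deer, sign: positive}
  - {cause: tri, effect: red_deer, sign: negative}
  - {cause: elevation, effect: red_deer, sign: negative}
  # roe deer
  - {cause: elevation, effect: roe_deer, sign: negative}
  - {cause: tri, effect: roe_deer, sign: negative}
  - {cause: forest, effect: roe_deer, sign: negative}
  # wild boar
  - {cause: tri, effect: wild_boar, sign: negative}
  - {cause: road_density, effect: wild_boar, sign: negative}
  - {cause: elevation, effect: wild_boar, sign: negative}
  - {cause: forest, effect: wild_boar, sign: negative}
correlated_errors: []
whitelist: []
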