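{
 "XMOD": {
  "form": "sum over skeletal atoms of c0 + c1*delta + c2*is_oxygen + c3*h; 0 for molecules without skeletal bonds",
  "coefficients": [
   2.124292929292932,
   0.2997878787878781,
   0.18661616161616362,
   0.31312121212120847
  ]
 },
 "P_VSA_p_1": {
  "form": "sum over skeletal atoms of per-class contributions; class = element|charge|degree|h-count|aromatic",
  "per_class": {
   "C|q+0|d2|h1|ar0": -0.47239639905546055,
   "C|q+0|d2|h1|ar1": 10.321028985507253,
   "C|q+0|d2|h2|ar0": 3.8564228158205176,
   "C|q+0|d3|h0|ar0": 0.6044446576150959,
   "C|q+0|d3|h0|ar1": 3.7531014492753636,
   "C|q+0|d3|h1|ar0": 8.579364029909492,
   "C|q+0|d4|h0|ar0": 1.5101002558047827,
   "O|q+0|d0|h2|ar0": 0.0,
   "O|q+0|d1|h0|ar0": 0.13204825855963626,
   "O|q+0|d1|h1|ar0": 8.912893841007493,
   "O|q+0|d2|h0|ar0": 3.92585610979925,
   "O|q+1|d2|h0|ar1": 0.9382753623188408
  }
 },
 "SAtot": {
  "form": "sum over skeletal atoms of per-class contributions; class = element|charge|degree|h-count|aromatic",
  "per_class": {
   "C|q+0|d2|h1|ar0": 5.9992231404959355,
   "C|q+0|d2|h1|ar1": 20.66660869565218,
   "C|q+0|d2|h2|ar0": 13.177987603305745,
   "C|q+0|d3|h0|ar0": 13.326111570247916,
   "C|q+0|d3|h0|ar1": 7.5151304347826136,
   "C|q+0|d3|h1|ar0": 19.449399449035813,
   "C|q+0|d4|h0|ar0": 3.8736005509641482,
   "O|q+0|d0|h2|ar0": 58.19599999999999,
   "O|q+0|d1|h0|ar0": 19.325334710743853,
   "O|q+0|d1|h1|ar0": 43.216771349862306,
   "O|q+0|d2|h0|ar0": -1.7053099173554738,
   "O|q+1|d2|h0|ar1": 1.878782608695653
  }
 },
 "VvdwMG": {
  "form": "sum over skeletal atoms of per-class contributions; class = element|charge|degree|h-count|aromatic",
  "per_class": {
   "C|q+0|d2|h1|ar0": 0.4163223140496122,
   "C|q+0|d2|h1|ar1": 9.128086956521747,
   "C|q+0|d2|h2|ar0": 4.803148760330558,
   "C|q+0|d3|h0|ar0": 4.633661157024783,
   "C|q+0|d3|h0|ar1": 3.319304347826089,
   "C|q+0|d3|h1|ar0": 5.125873278236918,
   "C|q+0|d4|h0|ar0": 1.9771267217630697,
   "O|q+0|d0|h2|ar0": 14.766999999999998,
   "O|q+0|d1|h0|ar0": 5.0499834710743965,
   "O|q+0|d1|h1|ar0": 11.720410468319576,
   "O|q+0|d2|h0|ar0": 1.2977190082644248,
   "O|q+1|d2|h0|ar1": 0.829826086956522
  }
 },
 "PDI": {
  "form": "sum over skeletal atoms of per-class contributions; class = element|charge|degree|h-count|aromatic",
  "per_class": {
   "C|q+0|d2|h1|ar0": 0.03977626918536031,
   "C|q+0|d2|h1|ar1": 0.08337681159420293,
   "C|q+0|d2|h2|ar0": 0.00537750885478144,
   "C|q+0|d3|h0|ar0": 0.031102420306965646,
   "C|q+0|d3|h0|ar1": 0.03031884057971017,
   "C|q+0|d3|h1|ar0": 0.012081857536403019,
   "C|q+0|d4|h0|ar0": -0.008010428964974578,
   "O|q+0|d0|h2|ar0": 0.47799999999999987,
   "O|q+0|d1|h0|ar0": 0.07087868949232601,
   "O|q+0|d1|h1|ar0": 0.09332802046438426,
   "O|q+0|d2|h0|ar0": -0.0551337072018894,
   "O|q+1|d2|h0|ar1": 0.00757971014492754
  }
 },
 "calibration_anchors": {
  "components": [
   "water",
   "citric_acid",
   "glucose",
   "sucrose",
   "anthocyanin"
  ],
  "note": "fitted to the published five-component descriptor table"
 }
}
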