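{
 "architecture": "3-10-1",
 "b1": [
  -0.9216212615086402,
  0.959462247478679,
  1.6592212316504114,
  1.7653105520804402,
  -0.20847967320013275,
  0.9302301628720273,
  0.6240405899749673,
  -1.5313433018124256,
  1.0420931063191565,
  1.100144069419419
 ],
 "b2": 0.8957301820064187,
 "feature_max": [
  1.0,
  1.0,
  1.0
 ],
 "feature_min": [
  0.0,
  0.0,
  0.0
 ],
 "fuzzy_rule_version": "tri3-sumquality-v1",
 "seed": 20151024,
 "w1": [
  [
   0.8968950222472631,
   0.40143519639066405,
   0.27749057141530553,
   -0.24629740897921684,
   2.116466425013231,
   -0.6365174839322805,
   0.6445735332104048,
   3.5684727605698416,
   0.5040815943114232,
   0.3377920137479899
  ],
  [
   2.241621977122844,
   2.5272407331561517,
   0.6312656619189562,
   -0.6064267732664099,
   2.5008374522975845,
   0.3155253365595813,
   0.7594975860367021,
   4.127499485051479,
   -0.713424391729451,
   -0.130295988016262
  ],
  [
   0.8300987586789932,
   1.2506181540479144,
   0.5859546252173062,
   -2.316505225365559,
   1.769266945966381,
   -0.12624869771967245,
   0.6868506630346934,
   3.5366436349903982,
   -1.4003266985098877,
   0.1503693125015994
  ]
 ],
 "w2": [
  -1.3144715526335091,
  1.3643579584039789,
  -0.35950175546984486,
  1.0838166828938933,
  2.758577863289381,
  -0.9388311231122661,
  0.05753945992155211,
  -1.5795241788589547,
  -1.284994032884739,
  -1.0491613486567677
 ]
}
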