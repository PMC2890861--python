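{
 "bands": [
  "1-4",
  "5-8",
  "9-12",
  "13-16",
  "17-20",
  "20+"
 ],
 "vigour": [
  "low",
  "moderate",
  "high"
 ],
 "counts": [
  [
   153,
   52,
   32,
   14,
   15,
   21
  ],
  [
   334,
   116,
   47,
   40,
   14,
   40
  ],
  [
   544,
   307,
   198,
   124,
   79,
   197
  ]
 ]
}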