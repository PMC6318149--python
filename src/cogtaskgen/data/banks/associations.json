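[
  {"left": "hammer", "right": "nail"},
  {"left": "key", "right": "lock"},
  {"left": "needle", "right": "thread"},
  {"left": "cup", "right": "saucer"},
  {"left": "toothbrush", "right": "toothpaste"},
  {"left": "shoe", "right": "shoelace"},
  {"left": "pen", "right": "paper"},
  {"left": "pillow", "right": "bed"},
  {"left": "umbrella", "right": "rain"},
  {"left": "candle", "right": "match"},
  {"left": "broom", "right": "dustpan"},
  {"left": "pot", "right": "lid"},
  {"left": "letter", "right": "envelope"},
  {"left": "guitar", "right": "strings"},
  {"left": "camera", "right": "photograph"},
  {"left": "soap", "right": "towel"}
]
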