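{
  "fruits": ["apple", "pear", "banana", "orange", "grape", "cherry", "plum", "peach"],
  "animals": ["dog", "cat", "horse", "rabbit", "sheep", "duck", "pig", "goat"],
  "tools": ["hammer", "saw", "screwdriver", "pliers", "drill", "wrench", "chisel", "file"],
  "clothing": ["shirt", "trousers", "jacket", "skirt", "sweater", "coat", "socks", "dress"],
  "vehicles": ["car", "bus", "bicycle", "train", "motorcycle", "truck", "tram", "boat"],
  "furniture": ["table", "chair", "sofa", "wardrobe", "bookshelf", "bed", "stool", "desk"],
  "professions": ["doctor", "teacher", "baker", "carpenter", "nurse", "farmer", "pilot", "cook"],
  "instruments": ["guitar", "piano", "violin", "flute", "drum", "trumpet", "harp", "accordion"]
}
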