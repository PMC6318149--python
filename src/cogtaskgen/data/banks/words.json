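[
  {"word": "apple", "picture": "img:apple"},
  {"word": "bread", "picture": "img:bread"},
  {"word": "chair", "picture": "img:chair"},
  {"word": "table", "picture": "img:table"},
  {"word": "window", "picture": "img:window"},
  {"word": "garden", "picture": "img:garden"},
  {"word": "flower", "picture": "img:flower"},
  {"word": "bottle", "picture": "img:bottle"},
  {"word": "candle", "picture": "img:candle"},
  {"word": "mirror", "picture": "img:mirror"},
  {"word": "pillow", "picture": "img:pillow"},
  {"word": "carpet", "picture": "img:carpet"},
  {"word": "basket", "picture": "img:basket"},
  {"word": "orange", "picture": "img:orange"},
  {"word": "banana", "picture": "img:banana"},
  {"word": "tomato", "picture": "img:tomato"},
  {"word": "potato", "picture": "img:potato"},
  {"word": "onion", "picture": "img:onion"},
  {"word": "lemon", "picture": "img:lemon"},
  {"word": "grape", "picture": "img:grape"},
  {"word": "melon", "picture": "img:melon"},
  {"word": "spoon", "picture": "img:spoon"},
  {"word": "knife", "picture": "img:knife"},
  {"word": "plate", "picture": "img:plate"},
  {"word": "glass", "picture": "img:glass"},
  {"word": "clock", "picture": "img:clock"},
  {"word": "radio", "picture": "img:radio"},
  {"word": "phone", "picture": "img:phone"},
  {"word": "shirt", "picture": "img:shirt"},
  {"word": "shoes", "picture": "img:shoes"},
  {"word": "scarf", "picture": "img:scarf"},
  {"word": "glove", "picture": "img:glove"},
  {"word": "house", "picture": "img:house"},
  {"word": "train", "picture": "img:train"},
  {"word": "plane", "picture": "img:plane"},
  {"word": "beach", "picture": "img:beach"},
  {"word": "river", "picture": "img:river"},
  {"word": "cloud", "picture": "img:cloud"},
  {"word": "horse", "picture": "img:horse"},
  {"word": "sheep", "picture": "img:sheep"},
  {"word": "mouse", "picture": "img:mouse"},
  {"word": "tiger", "picture": "img:tiger"},
  {"word": "eagle", "picture": "img:eagle"},
  {"word": "snake", "picture": "img:snake"},
  {"word": "bridge", "picture": "img:bridge"},
  {"word": "church", "picture": "img:church"},
  {"word": "market", "picture": "img:market"},
  {"word": "school", "picture": "img:school"},
  {"word": "doctor", "picture": "img:doctor"},
  {"word": "nurse", "picture": "img:nurse"},
  {"word": "baker", "picture": "img:baker"},
  {"word": "singer", "picture": "img:singer"},
  {"word": "winter", "picture": "img:winter"},
  {"word": "summer", "picture": "img:summer"},
  {"word": "autumn", "picture": "img:autumn"},
  {"word": "spring", "picture": "img:spring"},
  {"word": "monday", "picture": "img:monday"},
  {"word": "sunday", "picture": "img:sunday"},
  {"word": "coffee", "picture": "img:coffee"},
  {"word": "butter", "picture": "img:butter"},
  {"word": "cheese", "picture": "img:cheese"},
  {"word": "pepper", "picture": "img:pepper"},
  {"word": "sugar", "picture": "img:sugar"},
  {"word": "honey", "picture": "img:honey"}
]
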