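[
  {
    "id": "kitchen",
    "title": "A kitchen in the morning",
    "asset": "img:scene-kitchen",
    "facts": [
      {"template": "The kettle is on the {}.", "correct": "stove", "foils": ["floor", "windowsill", "chair", "refrigerator"]},
      {"template": "There are two {} on the table.", "correct": "cups", "foils": ["umbrellas", "pillows", "shoes", "books"]},
      {"template": "The window above the sink is {}.", "correct": "open", "foils": ["broken", "painted red", "covered with snow", "missing"]},
      {"template": "A {} is hanging next to the oven.", "correct": "towel", "foils": ["coat", "painting", "mirror", "clock"]},
      {"template": "The refrigerator door is {}.", "correct": "closed", "foils": ["open", "missing", "lying on the floor", "painted black"]},
      {"template": "There is a bowl of {} on the counter.", "correct": "fruit", "foils": ["keys", "letters", "soap", "coins"]},
      {"template": "The cat is sleeping on the {}.", "correct": "chair", "foils": ["stove", "kitchen table", "refrigerator", "windowsill"]},
      {"template": "A loaf of {} sits on the cutting board.", "correct": "bread", "foils": ["soap", "cheese", "paper", "wood"]}
    ]
  },
  {
    "id": "supermarket",
    "title": "At the supermarket",
    "asset": "img:scene-supermarket",
    "facts": [
      {"template": "A woman is pushing a {}.", "correct": "shopping cart", "foils": ["wheelbarrow", "bicycle", "pram full of bread", "ladder"]},
      {"template": "The apples are stacked near the {}.", "correct": "entrance", "foils": ["checkout", "freezer", "exit door", "storage room"]},
      {"template": "The cashier is wearing a {} apron.", "correct": "green", "foils": ["red", "black", "yellow", "striped"]},
      {"template": "There is a queue of {} people at the checkout.", "correct": "three", "foils": ["ten", "zero", "twenty", "seven"]},
      {"template": "The milk is kept in the {} aisle.", "correct": "refrigerated", "foils": ["bakery", "vegetable", "cleaning", "toy"]},
      {"template": "A sign announces a discount on {}.", "correct": "oranges", "foils": ["televisions", "shoes", "newspapers", "furniture"]},
      {"template": "A boy is holding a box of {}.", "correct": "cereal", "foils": ["nails", "candles", "envelopes", "gloves"]},
      {"template": "The bread shelf is next to the {}.", "correct": "pastry counter", "foils": ["fish counter", "exit", "car park", "flower stand"]}
    ]
  },
  {
    "id": "park",
    "title": "An afternoon in the park",
    "asset": "img:scene-park",
    "facts": [
      {"template": "Two children are playing with a {}.", "correct": "ball", "foils": ["hammer", "suitcase", "broom", "kettle"]},
      {"template": "An old man is sitting on a {}.", "correct": "bench", "foils": ["swing", "fountain", "bicycle", "tree branch"]},
      {"template": "The fountain is in the {} of the park.", "correct": "center", "foils": ["car park", "corner by the gate", "playground", "pond"]},
      {"template": "A {} dog is chasing pigeons.", "correct": "small", "foils": ["sleeping", "swimming", "purple", "caged"]},
      {"template": "The flower beds are full of {}.", "correct": "tulips", "foils": ["cacti", "pumpkins", "reeds", "mushrooms"]},
      {"template": "A vendor is selling {} near the gate.", "correct": "ice cream", "foils": ["furniture", "car tyres", "umbrellas", "firewood"]},
      {"template": "A woman is reading a {} under a tree.", "correct": "newspaper", "foils": ["map of the sea", "menu", "recipe", "ticket"]},
      {"template": "The path around the lake is made of {}.", "correct": "gravel", "foils": ["glass", "carpet", "sand dunes", "ice"]}
    ]
  },
  {
    "id": "busstop",
    "title": "At the bus stop",
    "asset": "img:scene-busstop",
    "facts": [
      {"template": "The timetable is fixed to the {}.", "correct": "pole", "foils": ["ground", "tree", "bus door", "bench seat"]},
      {"template": "A man is carrying a {} umbrella.", "correct": "black", "foils": ["transparent", "broken", "giant beach", "paper"]},
      {"template": "The next bus goes to the {}.", "correct": "city center", "foils": ["airport", "harbor", "mountains", "stadium"]},
      {"template": "A girl is listening to music with {}.", "correct": "headphones", "foils": ["a radio on her shoulder", "a trumpet", "earmuffs", "a seashell"]},
      {"template": "The shelter has a {} roof.", "correct": "glass", "foils": ["straw", "missing", "grass", "tile"]},
      {"template": "An advertisement shows a bottle of {}.", "correct": "orange juice", "foils": ["motor oil", "perfume", "shampoo", "ink"]},
      {"template": "The rubbish bin is {} the bench.", "correct": "beside", "foils": ["on top of", "under", "inside", "hanging above"]},
      {"template": "A cyclist is waiting at the {} light.", "correct": "red", "foils": ["green", "blue", "broken", "flashing purple"]}
    ]
  },
  {
    "id": "doctorsoffice",
    "title": "In the doctor's waiting room",
    "asset": "img:scene-doctorsoffice",
    "facts": [
      {"template": "The receptionist sits behind a {} desk.", "correct": "white", "foils": ["glass-bottomed", "broken", "floating", "golden"]},
      {"template": "Magazines are piled on a low {}.", "correct": "table", "foils": ["stool in the corridor", "radiator", "window ledge", "wheelchair"]},
      {"template": "A poster on the wall explains how to wash your {}.", "correct": "hands", "foils": ["car", "dog", "windows", "clothes"]},
      {"template": "Three patients are {} in the waiting room.", "correct": "sitting", "foils": ["dancing", "sleeping on the floor", "running", "singing"]},
      {"template": "The scale stands next to the {}.", "correct": "door", "foils": ["fish tank", "coffee machine", "coat rack outside", "reception desk"]},
      {"template": "A child is playing with a toy {}.", "correct": "train", "foils": ["stethoscope", "syringe", "ladder", "lawnmower"]},
      {"template": "The clock on the wall shows {} o'clock.", "correct": "ten", "foils": ["midnight", "three", "seven", "five"]},
      {"template": "A nurse is carrying a tray of {}.", "correct": "files", "foils": ["sandwiches", "flowers", "paint cans", "cutlery"]}
    ]
  },
  {
    "id": "livingroom",
    "title": "A living room in the evening",
    "asset": "img:scene-livingroom",
    "facts": [
      {"template": "A {} lamp lights the reading corner.", "correct": "floor", "foils": ["traffic", "street", "pocket", "bicycle"]},
      {"template": "The television shows a {} program.", "correct": "cooking", "foils": ["diving", "blank", "flight-training", "weather-from-Mars"]},
      {"template": "Grandfather is asleep in the {}.", "correct": "armchair", "foils": ["bathtub", "doorway", "bookshelf", "window"]},
      {"template": "A chessboard is set up on the {}.", "correct": "coffee table", "foils": ["floor lamp", "piano stool", "television", "radiator"]},
      {"template": "The curtains are {}.", "correct": "drawn", "foils": ["on fire", "missing", "soaking wet", "tied in knots"]},
      {"template": "Family photos hang above the {}.", "correct": "sofa", "foils": ["refrigerator", "front door", "fireplace tools", "aquarium"]},
      {"template": "A cat and a {} share the rug.", "correct": "dog", "foils": ["goat", "peacock", "turtle", "pony"]},
      {"template": "A bowl of {} stands on the sideboard.", "correct": "walnuts", "foils": ["screws", "marbles", "stamps", "buttons"]}
    ]
  }
]
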