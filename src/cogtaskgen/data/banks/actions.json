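[
  {
    "goal": "Make a cup of tea",
    "steps": [
      "Fill the kettle with water",
      "Turn on the kettle",
      "Put a tea bag in the cup",
      "Wait for the water to boil",
      "Pour the hot water into the cup",
      "Let the tea steep for three minutes",
      "Remove the tea bag",
      "Add sugar and stir"
    ]
  },
  {
    "goal": "Do the laundry",
    "steps": [
      "Sort the clothes by color",
      "Put the clothes in the washing machine",
      "Add the detergent",
      "Select the washing program",
      "Start the machine",
      "Take out the wet clothes",
      "Hang the clothes to dry",
      "Fold the dry clothes"
    ]
  },
  {
    "goal": "Go grocery shopping",
    "steps": [
      "Write a shopping list",
      "Take the shopping bags",
      "Walk to the supermarket",
      "Pick the items on the list",
      "Go to the checkout",
      "Pay for the groceries",
      "Pack the groceries in the bags",
      "Carry the bags home"
    ]
  },
  {
    "goal": "Brush your teeth",
    "steps": [
      "Pick up the toothbrush",
      "Wet the toothbrush",
      "Put toothpaste on the brush",
      "Brush the upper teeth",
      "Brush the lower teeth",
      "Rinse your mouth with water",
      "Rinse the toothbrush",
      "Put the toothbrush away"
    ]
  },
  {
    "goal": "Make a sandwich",
    "steps": [
      "Take two slices of bread",
      "Spread butter on the bread",
      "Add a slice of cheese",
      "Add a slice of ham",
      "Add lettuce and tomato",
      "Put the slices together",
      "Cut the sandwich in half",
      "Put the sandwich on a plate"
    ]
  },
  {
    "goal": "Pay a bill at the post office",
    "steps": [
      "Find the bill at home",
      "Put the bill in your bag",
      "Walk to the post office",
      "Take a queue ticket",
      "Wait for your number",
      "Hand the bill to the clerk",
      "Pay the amount due",
      "Keep the payment receipt"
    ]
  },
  {
    "goal": "Plant a flower",
    "steps": [
      "Fill the pot with soil",
      "Make a small hole in the soil",
      "Place the seed in the hole",
      "Cover the seed with soil",
      "Water the soil gently",
      "Put the pot near a window",
      "Water the plant every day",
      "Watch the flower grow"
    ]
  },
  {
    "goal": "Take the bus downtown",
    "steps": [
      "Check the bus timetable",
      "Walk to the bus stop",
      "Wait for the right bus",
      "Signal the driver to stop",
      "Board the bus",
      "Validate the ticket",
      "Press the stop button near your stop",
      "Get off the bus"
    ]
  }
]
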