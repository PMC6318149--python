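[
  {"ops": ["+"], "text": "Rosa bought {0} stamps on Monday and {1} stamps on Tuesday. How many stamps did she buy altogether?"},
  {"ops": ["+"], "text": "There are {0} chairs in the dining room and {1} chairs on the balcony. How many chairs are there in the house?"},
  {"ops": ["-"], "text": "Daniel had {0} euros in his wallet and spent {1} euros at the pharmacy. How much money does he have left?"},
  {"ops": ["-"], "text": "A basket held {0} oranges; {1} of them were eaten at breakfast. How many oranges remain in the basket?"},
  {"ops": ["+", "+"], "text": "Clara picked {0} tomatoes on Friday, {1} on Saturday and {2} on Sunday. How many tomatoes did she pick over the weekend?"},
  {"ops": ["+", "-"], "text": "A bus left the station with {0} passengers. At the first stop {1} people got on and {2} got off. How many passengers are on the bus now?"},
  {"ops": ["-", "+"], "text": "The baker made {0} rolls, sold {1} before noon, and baked another {2} in the afternoon. How many rolls does he have now?"},
  {"ops": ["+", "+", "-"], "text": "Miguel saved {0} euros in March, {1} euros in April and {2} euros in May, then spent {3} euros on a coat. How many euros are left?"},
  {"ops": ["+", "-", "+"], "text": "A library received {0} new books, added {1} donated ones, lent out {2}, and then received another {3}. How many of these books are in the library now?"},
  {"ops": ["-", "+", "-"], "text": "A water tank held {0} liters. {1} liters were used for the garden, {2} liters of rain were collected, and {3} liters went to the animals. How many liters remain?"},
  {"ops": ["+", "+", "-", "-"], "text": "Helena collected {0} bottles on Monday, {1} on Tuesday and {2} on Wednesday, then returned {3} to the shop and gave {4} to a neighbour. How many bottles does she still have?"},
  {"ops": ["+", "-", "+", "-"], "text": "A parking lot had {0} cars. In the morning {1} cars arrived and {2} left; after lunch {3} more arrived and {4} left. How many cars are parked now?"},
  {"ops": ["-", "+", "-", "+"], "text": "The grocer had {0} melons, sold {1}, received a delivery of {2}, sold another {3}, and took back {4} from the display. How many melons does the grocer have?"}
]
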