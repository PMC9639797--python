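"""Built-in synthetic story stimuli for recall simulation.

These three short narratives are synthetic stand-ins written for this
package: structurally similar everyday stories with named people, places and
a chain of concrete events, the kind of material used in story-recall
testing.  They carry no claim of equivalence to any published stimulus set.
"""

SYNTHETIC_STORIES: tuple[str, ...] = (
    # Story 1
    "Anna Clarke left her house on Mill Road early on Tuesday morning to "
    "catch the train to Manchester. At the station she realised she had "
    "forgotten her purse on the kitchen table, so she borrowed ten pounds "
    "from her neighbour George, who was travelling on the same platform. "
    "On the train she read a newspaper article about a flower show and "
    "decided to buy tulips for her sister Margaret. When she arrived she "
    "took the number four bus to the hospital, where Margaret was "
    "recovering from an operation on her knee. The tulips were yellow and "
    "red, and Margaret laughed because yellow had been their mother's "
    "favourite colour. Before leaving, Anna promised to return on Friday "
    "with photographs from their cousin's wedding in Bristol.",
    # Story 2
    "Daniel Reyes worked as a baker in a small shop near the harbour in "
    "Portsmouth. One Saturday in October the oven broke down just before "
    "six in the morning, while forty loaves were still rising on the "
    "counter. Daniel telephoned his brother Martin, an electrician, who "
    "drove across town in the rain with a box of tools. Together they "
    "replaced a burnt fuse and cleaned the fan, and the first bread came "
    "out only an hour late. A regular customer, an elderly teacher named "
    "Mrs Hall, waited outside under a green umbrella and was given a free "
    "cinnamon bun for her patience. That evening Daniel wrote the date on "
    "the fuse box with chalk so he would remember when the repair was "
    "done.",
    # Story 3
    "On a warm evening in June, Priya Sharma organised a small concert in "
    "the village hall at Oakfield to raise money for the local library. "
    "Her father carried two crates of lemonade from the car, and her "
    "friend Tom hung paper lanterns above the stage. The first performer "
    "was a schoolgirl who played the violin, followed by a choir of "
    "twelve singers from the next town. Halfway through the concert the "
    "lights failed, so the audience lit candles and the choir sang on in "
    "the dark, which everyone later agreed was the best part. The event "
    "raised three hundred and twenty pounds, enough to buy a new reading "
    "desk and repair the library's leaking window.",
)
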