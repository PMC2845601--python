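{
  "classes": [
    {"name": "Seed", "subclasses": [
      {"name": "No germination", "reported_plants": 3904},
      {"name": "Seedling lethality", "reported_plants": 1674}
    ]},
    {"name": "Cotyledons", "subclasses": [
      {"name": "Colour", "reported_plants": 264},
      {"name": "Number", "reported_plants": 82},
      {"name": "Morphology", "reported_plants": 17},
      {"name": "Size", "reported_plants": 2},
      {"name": "Other cotyledon development", "reported_plants": 3}
    ]},
    {"name": "Plant size", "subclasses": [
      {"name": "Small plant", "reported_plants": 303},
      {"name": "Large plant", "reported_plants": 4}
    ]},
    {"name": "Plant habit", "subclasses": [
      {"name": "Aborted growth", "reported_plants": 81},
      {"name": "Branching", "reported_plants": 109},
      {"name": "Internode length", "reported_plants": 16},
      {"name": "Other plant habit", "reported_plants": 174}
    ]},
    {"name": "Leaf morphology", "subclasses": [
      {"name": "Leaf complexity", "reported_plants": 27},
      {"name": "Leaf size", "reported_plants": 98},
      {"name": "Leaf texture", "reported_plants": 16},
      {"name": "Leaf width", "reported_plants": 12},
      {"name": "Other leaf development", "reported_plants": 188}
    ]},
    {"name": "Leaf colour", "subclasses": [
      {"name": "Dark green leaf", "reported_plants": 19},
      {"name": "Dull green/grey leaf", "reported_plants": 19},
      {"name": "Purple leaf", "reported_plants": 17},
      {"name": "Variegation", "reported_plants": 20},
      {"name": "White leaf", "reported_plants": 4},
      {"name": "Yellow leaf", "reported_plants": 28},
      {"name": "Yellow-green leaf", "reported_plants": 79}
    ]},
    {"name": "Flowering", "subclasses": [
      {"name": "Late flowering", "reported_plants": 142}
    ]},
    {"name": "Inflorescence", "subclasses": [
      {"name": "Inflorescence structure", "reported_plants": 28}
    ]},
    {"name": "Flower morphology", "subclasses": [
      {"name": "Flower homeotic mutation", "reported_plants": 5},
      {"name": "Flower organ size", "reported_plants": 10},
      {"name": "Flower organ width", "reported_plants": 12},
      {"name": "Other flower morphology", "reported_plants": 4}
    ]},
    {"name": "Flower colour", "subclasses": [
      {"name": "Pale yellow flower", "reported_plants": 13},
      {"name": "White flower", "reported_plants": 5}
    ]},
    {"name": "Fruit size", "subclasses": [
      {"name": "Large fruit", "reported_plants": 212},
      {"name": "Small fruit", "reported_plants": 192}
    ]},
    {"name": "Fruit morphology", "subclasses": [
      {"name": "Long fruit", "reported_plants": 43},
      {"name": "Other fruit morphology", "reported_plants": 2},
      {"name": "Rounded fruit", "reported_plants": 4}
    ]},
    {"name": "Fruit colour", "subclasses": [
      {"name": "Dark red fruit", "reported_plants": 0},
      {"name": "Green fruit", "reported_plants": 0},
      {"name": "Orange fruit", "reported_plants": 0},
      {"name": "Yellow fruit", "reported_plants": 3}
    ]},
    {"name": "Fruit number", "subclasses": [
      {"name": "Absent", "reported_plants": 1073},
      {"name": "Few", "reported_plants": 1393},
      {"name": "Many", "reported_plants": 64}
    ]},
    {"name": "Sterility", "subclasses": [
      {"name": "Partial sterility", "reported_plants": 2125},
      {"name": "Total sterility", "reported_plants": 576}
    ]},
    {"name": "Seed germination into fruit", "subclasses": [
      {"name": "Seed germination into fruit", "reported_plants": 208}
    ]},
    {"name": "Disease and stress response", "subclasses": [
      {"name": "Necrosis", "reported_plants": 48},
      {"name": "Wilting", "reported_plants": 80},
      {"name": "Other disease response", "reported_plants": 0}
    ]}
  ]
}
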