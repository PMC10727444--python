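{
  "unpaved": ["path", "bridleway", "track"],
  "paved": [
    "motorway", "trunk", "primary", "secondary", "tertiary", "unclassified",
    "residential", "service", "living_street", "pedestrian", "footway",
    "cycleway", "steps", "road", "motorway_link", "trunk_link",
    "primary_link", "secondary_link", "tertiary_link"
  ]
}
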