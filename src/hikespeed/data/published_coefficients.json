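{
  "schema": "hikespeed-glm-coefficients-v1",
  "description": "Published fitted walking-speed GLM coefficients: v = exp(a + b*phi + c*theta + d*theta^2), v in km/h, slopes in degrees.",
  "coefficients": {
    "paved_road":      {"a": 1.580, "b": -0.00389, "c": -0.00726, "d": -0.00218},
    "unpaved_road":    {"a": 1.580, "b": -0.00389, "c": -0.00965, "d": -0.00248},
    "offroad_unknown": {"a": 1.536, "b": -0.00731, "c": -0.00965, "d": -0.00187},
    "offroad_light":   {"a": 1.580, "b": -0.00731, "c": -0.00965, "d": -0.00187},
    "offroad_heavy":   {"a": 1.443, "b": -0.00731, "c": -0.00965, "d": -0.00187}
  }
}
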