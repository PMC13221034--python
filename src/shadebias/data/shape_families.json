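{
  "shapes": {
    "bathtub": {
      "family": "bathtub",
      "params": {
        "length": [1.0, 1.2],
        "width": [0.5, 0.62],
        "depth": [0.3, 0.4],
        "rim": [0.05, 0.09],
        "foot": [0.06, 0.1]
      }
    },
    "bear": {
      "family": "bear",
      "params": {
        "body": [0.5, 0.62],
        "head": [0.26, 0.34],
        "ear": [0.08, 0.13],
        "leg_len": [0.3, 0.42],
        "leg_r": [0.1, 0.14]
      }
    },
    "bird": {
      "family": "bird",
      "params": {
        "body_len": [0.5, 0.62],
        "body_fat": [0.26, 0.34],
        "head": [0.17, 0.23],
        "beak": [0.2, 0.3],
        "tail": [0.35, 0.5]
      }
    },
    "butterfly": {
      "family": "butterfly",
      "params": {
        "wing_span": [0.8, 1.0],
        "wing_chord": [0.6, 0.8],
        "body_len": [0.55, 0.7],
        "body_r": [0.06, 0.09],
        "dihedral": [5.0, 20.0]
      }
    },
    "elephant": {
      "family": "elephant",
      "params": {
        "body_len": [0.9, 1.1],
        "body_fat": [0.5, 0.6],
        "head": [0.26, 0.33],
        "trunk_len": [0.4, 0.55],
        "ear": [0.3, 0.45],
        "leg_len": [0.4, 0.55]
      }
    },
    "fish": {
      "family": "fish",
      "params": {
        "body_len": [0.85, 1.0],
        "body_fat": [0.2, 0.3],
        "body_height": [0.38, 0.5],
        "tail": [0.3, 0.42],
        "fin": [0.18, 0.28]
      }
    },
    "helmet": {
      "family": "helmet",
      "params": {
        "dome_w": [0.5, 0.6],
        "dome_h": [0.35, 0.45],
        "brim_r": [0.58, 0.7],
        "brim_t": [0.04, 0.08],
        "visor": [0.15, 0.25]
      }
    },
    "mailbox": {
      "family": "mailbox",
      "params": {
        "body_len": [0.7, 0.85],
        "body_w": [0.34, 0.44],
        "roof_r": [0.17, 0.23],
        "post_len": [0.7, 0.9],
        "flag": [0.2, 0.3]
      }
    },
    "mug": {
      "family": "mug",
      "params": {
        "radius": [0.3, 0.38],
        "height": [0.6, 0.75],
        "handle_w": [0.2, 0.28],
        "handle_t": [0.05, 0.08]
      }
    },
    "phone": {
      "family": "phone",
      "params": {
        "height": [0.8, 0.95],
        "width": [0.42, 0.52],
        "thickness": [0.06, 0.1],
        "button": [0.05, 0.09]
      }
    }
  },
  "textures": {
    "bathtub": {"pattern": "checker", "hue": 0.0},
    "bear": {"pattern": "blobs", "hue": 0.1},
    "bird": {"pattern": "hstripes", "hue": 0.2},
    "butterfly": {"pattern": "dots", "hue": 0.3},
    "elephant": {"pattern": "diag_grating", "hue": 0.4},
    "fish": {"pattern": "vstripes", "hue": 0.5},
    "helmet": {"pattern": "clouds", "hue": 0.6},
    "mailbox": {"pattern": "grid", "hue": 0.7},
    "mug": {"pattern": "antidiag_grating", "hue": 0.8},
    "phone": {"pattern": "speckle", "hue": 0.9}
  }
}
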