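{
 "midplane_landmark_ids": [
  1,
  4,
  5,
  38,
  39,
  40,
  41
 ],
 "points": [
  {
   "id": 1,
   "name": "Incisor",
   "role": "fixed",
   "side": "midline",
   "pair_id": 1,
   "curve_id": null
  },
  {
   "id": 2,
   "name": "Ento-left",
   "role": "fixed",
   "side": "left",
   "pair_id": 3,
   "curve_id": null
  },
  {
   "id": 3,
   "name": "Ento-right",
   "role": "fixed",
   "side": "right",
   "pair_id": 2,
   "curve_id": null
  },
  {
   "id": 4,
   "name": "Post-foramen",
   "role": "fixed",
   "side": "midline",
   "pair_id": 4,
   "curve_id": null
  },
  {
   "id": 5,
   "name": "Middle",
   "role": "fixed",
   "side": "midline",
   "pair_id": 5,
   "curve_id": null
  },
  {
   "id": 6,
   "name": "Curve sml left",
   "role": "curve",
   "side": "left",
   "pair_id": 10,
   "curve_id": "curve_left"
  },
  {
   "id": 7,
   "name": "Curve sml left",
   "role": "curve",
   "side": "left",
   "pair_id": 11,
   "curve_id": "curve_left"
  },
  {
   "id": 8,
   "name": "Curve sml left",
   "role": "curve",
   "side": "left",
   "pair_id": 12,
   "curve_id": "curve_left"
  },
  {
   "id": 9,
   "name": "Curve sml left",
   "role": "curve",
   "side": "left",
   "pair_id": 13,
   "curve_id": "curve_left"
  },
  {
   "id": 10,
   "name": "Curve sml right",
   "role": "curve",
   "side": "right",
   "pair_id": 6,
   "curve_id": "curve_right"
  },
  {
   "id": 11,
   "name": "Curve sml right",
   "role": "curve",
   "side": "right",
   "pair_id": 7,
   "curve_id": "curve_right"
  },
  {
   "id": 12,
   "name": "Curve sml right",
   "role": "curve",
   "side": "right",
   "pair_id": 8,
   "curve_id": "curve_right"
  },
  {
   "id": 13,
   "name": "Curve sml right",
   "role": "curve",
   "side": "right",
   "pair_id": 9,
   "curve_id": "curve_right"
  },
  {
   "id": 14,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 26,
   "curve_id": null
  },
  {
   "id": 15,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 27,
   "curve_id": null
  },
  {
   "id": 16,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 28,
   "curve_id": null
  },
  {
   "id": 17,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 29,
   "curve_id": null
  },
  {
   "id": 18,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 30,
   "curve_id": null
  },
  {
   "id": 19,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 31,
   "curve_id": null
  },
  {
   "id": 20,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 32,
   "curve_id": null
  },
  {
   "id": 21,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 33,
   "curve_id": null
  },
  {
   "id": 22,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 34,
   "curve_id": null
  },
  {
   "id": 23,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 35,
   "curve_id": null
  },
  {
   "id": 24,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 36,
   "curve_id": null
  },
  {
   "id": 25,
   "name": "Surface sml right",
   "role": "surface",
   "side": "right",
   "pair_id": 37,
   "curve_id": null
  },
  {
   "id": 26,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 14,
   "curve_id": null
  },
  {
   "id": 27,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 15,
   "curve_id": null
  },
  {
   "id": 28,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 16,
   "curve_id": null
  },
  {
   "id": 29,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 17,
   "curve_id": null
  },
  {
   "id": 30,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 18,
   "curve_id": null
  },
  {
   "id": 31,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 19,
   "curve_id": null
  },
  {
   "id": 32,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 20,
   "curve_id": null
  },
  {
   "id": 33,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 21,
   "curve_id": null
  },
  {
   "id": 34,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 22,
   "curve_id": null
  },
  {
   "id": 35,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 23,
   "curve_id": null
  },
  {
   "id": 36,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 24,
   "curve_id": null
  },
  {
   "id": 37,
   "name": "Surface sml left",
   "role": "surface",
   "side": "left",
   "pair_id": 25,
   "curve_id": null
  },
  {
   "id": 38,
   "name": "Curve sml middle",
   "role": "curve",
   "side": "midline",
   "pair_id": 38,
   "curve_id": "curve_middle"
  },
  {
   "id": 39,
   "name": "Curve sml middle",
   "role": "curve",
   "side": "midline",
   "pair_id": 39,
   "curve_id": "curve_middle"
  },
  {
   "id": 40,
   "name": "Curve sml middle",
   "role": "curve",
   "side": "midline",
   "pair_id": 40,
   "curve_id": "curve_middle"
  },
  {
   "id": 41,
   "name": "Curve sml middle",
   "role": "curve",
   "side": "midline",
   "pair_id": 41,
   "curve_id": "curve_middle"
  }
 ],
 "curves": [
  {
   "curve_id": "curve_left",
   "anchor_ids": [
    1,
    2
   ],
   "semilandmark_ids": [
    6,
    7,
    8,
    9
   ]
  },
  {
   "curve_id": "curve_right",
   "anchor_ids": [
    1,
    3
   ],
   "semilandmark_ids": [
    10,
    11,
    12,
    13
   ]
  },
  {
   "curve_id": "curve_middle",
   "anchor_ids": [
    4,
    5
   ],
   "semilandmark_ids": [
    38,
    39,
    40,
    41
   ]
  }
 ]
}
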