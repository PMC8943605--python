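{
 "description": "Two-component synthetic depth profile: a decaying sulfonate-like organic overlayer over a rising carbon-cluster substrate, negative polarity.",
 "components": [
  {
   "name": "sulfonates",
   "formulas": [
    "C8H9SO3",
    "C9H11SO3",
    "C10H13SO3",
    "C11H15SO3",
    "C12H17SO3",
    "C13H19SO3",
    "C14H21SO3",
    "C15H23SO3",
    "C16H25SO3",
    "C17H27SO3",
    "C18H29SO3",
    "C19H31SO3",
    "C20H33SO3",
    "C21H35SO3",
    "C22H37SO3",
    "C23H39SO3",
    "C24H41SO3",
    "C25H43SO3",
    "C26H45SO3",
    "C27H47SO3",
    "C28H49SO3",
    "C29H51SO3",
    "C30H53SO3",
    "C31H55SO3",
    "C32H57SO3",
    "C33H59SO3",
    "C34H61SO3",
    "C35H63SO3",
    "C36H65SO3",
    "C37H67SO3"
   ],
   "class_label": "sulfonate",
   "shape": "exp_decay",
   "shape_params": {
    "rate": 3.0
   },
   "base_intensity": 5000.0
  },
  {
   "name": "carbon_clusters",
   "formulas": [
    "C10",
    "C11",
    "C12",
    "C13",
    "C14",
    "C15",
    "C16",
    "C17",
    "C18",
    "C19",
    "C20",
    "C21",
    "C22",
    "C23",
    "C24",
    "C25",
    "C26",
    "C27",
    "C28",
    "C29",
    "C30",
    "C31",
    "C32",
    "C33",
    "C34",
    "C35",
    "C36",
    "C37",
    "C38",
    "C39"
   ],
   "class_label": "carbonaceous",
   "shape": "logistic_rise",
   "shape_params": {
    "midpoint": 0.5,
    "steepness": 10.0
   },
   "base_intensity": 8000.0
  }
 ],
 "noise": {
  "mz_sigma_ppm": 0.3,
  "intensity_sigma": 0.2,
  "noise_peak_rate": 20.0,
  "noise_mz_range": [
   80.0,
   700.0
  ],
  "decoy_intensity_frac": 0.05
 },
 "n_scans": 50,
 "seed": 42,
 "charge": -1,
 "constraints": {
  "elements": {
   "C": [
    0,
    100
   ],
   "H": [
    0,
    100
   ],
   "O": [
    0,
    3
   ],
   "S": [
    0,
    1
   ]
  },
  "tolerance": [
   [
    95,
    3
   ],
   [
    null,
    2
   ]
  ],
  "charge": -1
 }
}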