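{
 "version": 1,
 "task": "scale",
 "n_traj_per_level": 25,
 "seed": 20260101,
 "dialects": {
  "inertial": {
   "corruption": [
    0.0,
    0.1,
    0.2,
    0.35,
    0.5,
    0.75,
    1.0,
    1.5,
    2.0,
    3.0,
    4.0,
    6.0,
    8.0
   ],
   "smoothness": [
    9.414814718581939,
    9.074257913588227,
    8.269211263251997,
    7.243314326836892,
    6.490560248133165,
    5.655127809810827,
    5.132047756671045,
    4.335057479557063,
    3.755044237552107,
    3.090769070163018,
    2.7581639693167648,
    2.4437939294938014,
    2.4437939294938014
   ],
   "n_strokes": 2944
  },
  "optical": {
   "corruption": [
    0.0,
    0.1,
    0.2,
    0.35,
    0.5,
    0.75,
    1.0,
    1.5,
    2.0,
    3.0,
    4.0,
    6.0,
    8.0
   ],
   "smoothness": [
    8.155569596263557,
    7.956537219443353,
    7.667319357515805,
    6.967763417116905,
    6.46789303089596,
    5.70260857145546,
    5.213187075721719,
    4.404227438511727,
    3.900062810298249,
    3.1618280150980502,
    2.756795412969268,
    2.5084950044331236,
    2.5084950044331236
   ],
   "n_strokes": 2922
  }
 }
}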