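{
 "kawasaki": [
  {
   "input": {
    "sex": "F",
    "age": 33.2,
    "weight": 80.5,
    "height": 156.6,
    "spot_na": 38.5,
    "spot_k": 26.3,
    "spot_creat": 80.4
   },
   "expected_mg_per_day": 2908.1235434356468
  },
  {
   "input": {
    "sex": "M",
    "age": 56.1,
    "weight": 69.9,
    "height": 171.7,
    "spot_na": 177.2,
    "spot_k": 87.6,
    "spot_creat": 73.4
   },
   "expected_mg_per_day": 7222.369657417046
  },
  {
   "input": {
    "sex": "F",
    "age": 36.1,
    "weight": 86.2,
    "height": 174.1,
    "spot_na": 66.5,
    "spot_k": 20.2,
    "spot_creat": 221.9
   },
   "expected_mg_per_day": 2411.706650324094
  },
  {
   "input": {
    "sex": "F",
    "age": 67.9,
    "weight": 50.3,
    "height": 169.2,
    "spot_na": 92.0,
    "spot_k": 25.4,
    "spot_creat": 148.3
   },
   "expected_mg_per_day": 2797.89856292805
  },
  {
   "input": {
    "sex": "M",
    "age": 70.7,
    "weight": 60.3,
    "height": 169.5,
    "spot_na": 100.4,
    "spot_k": 64.3,
    "spot_creat": 144.3
   },
   "expected_mg_per_day": 3413.4705054216047
  }
 ],
 "tanaka": [
  {
   "input": {
    "sex": "M",
    "age": 59.1,
    "weight": 71.8,
    "height": 153.6,
    "spot_na": 152.6,
    "spot_k": 23.6,
    "spot_creat": 131.8
   },
   "expected_mg_per_day": 3478.081132580168
  },
  {
   "input": {
    "sex": "M",
    "age": 48.9,
    "weight": 92.9,
    "height": 154.9,
    "spot_na": 146.9,
    "spot_k": 79.7,
    "spot_creat": 130.3
   },
   "expected_mg_per_day": 3815.7964961508414
  },
  {
   "input": {
    "sex": "F",
    "age": 54.4,
    "weight": 62.1,
    "height": 184.9,
    "spot_na": 95.3,
    "spot_k": 41.0,
    "spot_creat": 137.8
   },
   "expected_mg_per_day": 3162.0697013703802
  },
  {
   "input": {
    "sex": "F",
    "age": 73.3,
    "weight": 96.0,
    "height": 183.5,
    "spot_na": 83.5,
    "spot_k": 51.3,
    "spot_creat": 137.8
   },
   "expected_mg_per_day": 3313.0786597555857
  },
  {
   "input": {
    "sex": "F",
    "age": 39.6,
    "weight": 73.0,
    "height": 168.0,
    "spot_na": 186.8,
    "spot_k": 51.7,
    "spot_creat": 67.4
   },
   "expected_mg_per_day": 5336.612143185086
  }
 ],
 "intersalt_with_k": [
  {
   "input": {
    "sex": "F",
    "age": 48.1,
    "weight": 74.5,
    "height": 158.6,
    "spot_na": 101.8,
    "spot_k": 63.0,
    "spot_creat": 197.6
   },
   "expected_mg_per_day": 2545.9507810557334
  },
  {
   "input": {
    "sex": "M",
    "age": 40.3,
    "weight": 77.9,
    "height": 191.4,
    "spot_na": 133.8,
    "spot_k": 71.1,
    "spot_creat": 240.0
   },
   "expected_mg_per_day": 2692.8862680809625
  },
  {
   "input": {
    "sex": "M",
    "age": 66.4,
    "weight": 84.1,
    "height": 190.3,
    "spot_na": 199.4,
    "spot_k": 66.5,
    "spot_creat": 178.2
   },
   "expected_mg_per_day": 4087.0095986972046
  },
  {
   "input": {
    "sex": "M",
    "age": 63.6,
    "weight": 104.2,
    "height": 192.3,
    "spot_na": 144.2,
    "spot_k": 90.2,
    "spot_creat": 60.9
   },
   "expected_mg_per_day": 4538.508486163248
  },
  {
   "input": {
    "sex": "M",
    "age": 53.8,
    "weight": 72.7,
    "height": 150.3,
    "spot_na": 140.2,
    "spot_k": 22.7,
    "spot_creat": 183.7
   },
   "expected_mg_per_day": 4330.391961543764
  }
 ],
 "intersalt_without_k": [
  {
   "input": {
    "sex": "F",
    "age": 32.1,
    "weight": 87.5,
    "height": 182.4,
    "spot_na": 120.4,
    "spot_k": 81.9,
    "spot_creat": 47.1
   },
   "expected_mg_per_day": 3246.6940237018534
  },
  {
   "input": {
    "sex": "F",
    "age": 39.8,
    "weight": 93.2,
    "height": 153.9,
    "spot_na": 170.2,
    "spot_k": 56.4,
    "spot_creat": 87.6
   },
   "expected_mg_per_day": 4182.484173430004
  },
  {
   "input": {
    "sex": "F",
    "age": 31.6,
    "weight": 54.9,
    "height": 158.6,
    "spot_na": 145.7,
    "spot_k": 97.1,
    "spot_creat": 217.2
   },
   "expected_mg_per_day": 2340.849273340868
  },
  {
   "input": {
    "sex": "F",
    "age": 40.4,
    "weight": 64.0,
    "height": 185.8,
    "spot_na": 140.2,
    "spot_k": 34.8,
    "spot_creat": 167.2
   },
   "expected_mg_per_day": 2400.6652225921707
  },
  {
   "input": {
    "sex": "F",
    "age": 27.1,
    "weight": 68.5,
    "height": 193.6,
    "spot_na": 115.7,
    "spot_k": 71.8,
    "spot_creat": 173.2
   },
   "expected_mg_per_day": 2073.93816944136
  }
 ],
 "mage": [
  {
   "input": {
    "sex": "F",
    "age": 39.8,
    "weight": 88.1,
    "height": 182.1,
    "spot_na": 68.8,
    "spot_k": 24.1,
    "spot_creat": 59.1
   },
   "expected_mg_per_day": 5377.991778773818
  },
  {
   "input": {
    "sex": "M",
    "age": 45.5,
    "weight": 63.1,
    "height": 152.1,
    "spot_na": 121.6,
    "spot_k": 82.0,
    "spot_creat": 145.7
   },
   "expected_mg_per_day": 2491.895350775441
  },
  {
   "input": {
    "sex": "M",
    "age": 44.1,
    "weight": 96.2,
    "height": 155.9,
    "spot_na": 71.0,
    "spot_k": 81.4,
    "spot_creat": 70.7
   },
   "expected_mg_per_day": 5714.414397493612
  },
  {
   "input": {
    "sex": "M",
    "age": 71.9,
    "weight": 57.1,
    "height": 163.0,
    "spot_na": 150.7,
    "spot_k": 41.3,
    "spot_creat": 92.8
   },
   "expected_mg_per_day": 4320.762265012669
  },
  {
   "input": {
    "sex": "M",
    "age": 49.6,
    "weight": 56.7,
    "height": 194.9,
    "spot_na": 157.0,
    "spot_k": 95.1,
    "spot_creat": 200.4
   },
   "expected_mg_per_day": 2255.4311481171844
  }
 ],
 "toft": [
  {
   "input": {
    "sex": "F",
    "age": 74.7,
    "weight": 65.0,
    "height": 153.0,
    "spot_na": 71.3,
    "spot_k": 88.0,
    "spot_creat": 69.7
   },
   "expected_mg_per_day": 2752.7733142037305
  },
  {
   "input": {
    "sex": "M",
    "age": 46.5,
    "weight": 74.9,
    "height": 180.8,
    "spot_na": 41.2,
    "spot_k": 75.9,
    "spot_creat": 104.8
   },
   "expected_mg_per_day": 1625.3871755725193
  },
  {
   "input": {
    "sex": "M",
    "age": 60.4,
    "weight": 93.8,
    "height": 163.4,
    "spot_na": 79.9,
    "spot_k": 54.3,
    "spot_creat": 127.5
   },
   "expected_mg_per_day": 3244.7296000000006
  },
  {
   "input": {
    "sex": "M",
    "age": 71.3,
    "weight": 106.7,
    "height": 180.3,
    "spot_na": 166.1,
    "spot_k": 85.8,
    "spot_creat": 68.4
   },
   "expected_mg_per_day": 14302.66701754386
  },
  {
   "input": {
    "sex": "F",
    "age": 74.2,
    "weight": 97.9,
    "height": 173.3,
    "spot_na": 126.5,
    "spot_k": 94.8,
    "spot_creat": 202.7
   },
   "expected_mg_per_day": 2529.413369511594
  }
 ]
}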