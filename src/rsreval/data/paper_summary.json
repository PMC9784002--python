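{
 "n": 31,
 "regressions": {
  "2009": {
   "needs": {
    "b": 0.132,
    "a": -0.37,
    "r": 0.798
   },
   "utilization": {
    "b": 0.136,
    "a": -0.029,
    "r": 0.693
   },
   "resources": {
    "b": 0.125,
    "a": -0.293,
    "r": 0.964
   }
  },
  "2019": {
   "needs": {
    "b": 0.126,
    "a": -0.36,
    "r": 0.849
   },
   "utilization": {
    "b": 0.113,
    "a": 0.281,
    "r": 0.444
   },
   "resources": {
    "b": 0.13,
    "a": -0.289,
    "r": 0.921
   }
  }
 },
 "cuts": {
  "2009": {
   "needs": [
    0.158,
    0.422
   ],
   "utilization": [
    0.514,
    0.785
   ],
   "resources": [
    0.208,
    0.458
   ]
  },
  "2019": {
   "needs": [
    0.142,
    0.392
   ],
   "utilization": [
    0.732,
    0.958
   ],
   "resources": [
    0.232,
    0.493
   ]
  }
 },
 "anova_F": {
  "2009": {
   "needs": 36.424,
   "utilization": 36.431,
   "resources": 36.363
  },
  "2019": {
   "needs": 36.565,
   "utilization": 36.306,
   "resources": 36.507
  }
 },
 "category_counts": {
  "2009": {
   "relative_balance": 16,
   "low_input": 3,
   "resource_shortage": 3,
   "overutilization": 5,
   "resource_waste": 4
  },
  "2019": {
   "relative_balance": 18,
   "low_input": 3,
   "resource_shortage": 0,
   "overutilization": 4,
   "resource_waste": 6
  }
 },
 "moved_into_balance": 8,
 "swapped_tie_cells": [
  [
   2009,
   "needs",
   "Guangdong"
  ],
  [
   2009,
   "needs",
   "Inner Mongolia"
  ],
  [
   2009,
   "needs",
   "Jiangsu"
  ],
  [
   2009,
   "needs",
   "Shandong"
  ],
  [
   2019,
   "resources",
   "Hunan"
  ],
  [
   2019,
   "resources",
   "Inner Mongolia"
  ]
 ]
}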