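model,Blog,FB,Movie,Cora,Citeseer,Cora2,Pubmed,Yeast,Human,Reddit,Amazon
BL_NODE,37.929,64.683,50.329,59.852,65.196,40.583,83.682,59.681,41.111,57.118,64.121
BL_NEIGH,19.746,51.413,35.601,77.43,70.181,63.862,83.16,53.522,60.939,59.699,66.236
GCN,34.068,50.397,39.059,76.969,72.991,63.956,85.722,62.565,58.298,75.667,61.777
GCN-S,39.101,63.682,51.194,77.523,71.903,63.152,86.432,60.34,62.057,77.637,73.746
GCN-MEAN,38.541,62.651,51.143,76.081,72.357,62.842,85.792,61.787,64.662,74.324,63.674
GS-MEAN,39.433,64.127,50.557,76.821,70.967,62.8,84.23,59.771,63.753,79.051,68.266
GS-MAX,40.275,64.571,50.569,73.272,71.39,53.476,85.087,62.727,65.068,78.203,70.302
GS-LSTM,37.744,64.619,41.261,65.73,63.788,38.617,82.577,58.353,64.231,63.169,68.024
NIP-MEAN,39.433,64.286,51.316,76.932,71.148,63.901,86.203,61.583,68.688,77.262,69.136
SS-ICA,38.517,64.349,52.433,75.342,68.973,63.098,84.798,68.444,43.629,81.92,65.789
I-NIP-MEAN,39.398,62.889,51.864,78.854,71.541,66.23,85.341,69.917,68.652,81.64,75.045
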