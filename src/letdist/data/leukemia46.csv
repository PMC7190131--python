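time,event
0.0301,1
0.0384,1
0.0630,1
0.0849,1
0.0877,1
0.0959,1
0.1397,1
0.1616,1
0.1699,1
0.2137,1
0.2137,1
0.2164,1
0.2384,1
0.2712,1
0.2740,1
0.3863,1
0.4384,1
0.4548,1
0.5918,1
0.6000,1
0.6438,1
0.6849,1
0.7397,1
0.8575,1
0.9096,1
0.9644,1
1.0082,1
1.2822,1
1.3452,1
1.4000,1
1.5260,1
1.7205,0
1.9890,0
2.2438,0
2.5068,0
2.6466,0
3.0384,1
3.1726,0
3.4411,1
4.4219,0
4.4356,0
4.5863,0
4.6904,0
4.7808,0
4.9863,0
5.0000,0
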