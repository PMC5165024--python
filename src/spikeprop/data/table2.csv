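# Reference cohort, spike-analysis results per patient.
# spike_density = spikes per channel per minute; frequency_moran /
# latency_moran = Moran Index of the spike-frequency and recruitment-latency
# maps; sequence_frequency = multichannel sequences per analyzed minute.
patient,spike_density,frequency_moran,total_sequences,sequence_frequency,latency_moran
Pt01,0.377,0.527,135,0.1283,0.501
Pt02,2.956,0.403,2224,6.5745,0.307
Pt03,6.578,0.284,739,4.8125,0.282
Pt04,2.386,0.589,774,1.7361,0.338
Pt05,5.085,0.427,1018,5.1247,0.411
Pt06,1.359,0.493,806,1.1831,0.349
Pt07,1.808,0.153,993,2.2260,0.182
Pt08,1.716,0.417,1076,2.3636,0.178
Pt09,4.552,0.488,1845,9.7421,0.451
Pt10,2.739,0.304,1680,4.2328,0.832
Pt11,10.685,0.705,2292,26.4504,0.368
Pt12,2.154,0.300,2652,6.2840,0.411
Pt13,0.992,0.335,916,0.8907,0.272
Pt14,1.206,0.525,1072,1.3445,0.151
Pt15,0.391,0.203,1323,0.5997,0.425
Pt16,0.904,0.465,1895,1.2681,0.437
Pt17,1.020,0.218,923,1.0076,0.316
Pt18,1.700,0.324,1240,1.7710,0.283
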