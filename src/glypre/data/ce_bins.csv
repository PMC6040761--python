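# Synthetic 23-bin CE-LIF map (default fixture).
# Migration windows are expressed in minutes relative to the internal-standard
# (APTS-maltose) apex. Bin members are desialylated compositions (sialic acids
# are cleaved before APTS labeling); bins with two members model co-migration.
# Windows are instrument-specific: this fixture is self-consistent with the
# synthetic trace generator and is replaceable by a laboratory bin map.
bin_label,offset_start,offset_end,members
A1+A2,4.62,4.98,N3H3;N4H3
M5,5.07,5.43,N2H5
FA2,5.52,5.88,N4H3F1
A1G1,5.97,6.33,N3H4
FA1G1,6.42,6.78,N3H4F1
M6+M5A1G1,6.87,7.23,N2H6;N3H6
A2G1,7.32,7.68,N4H4
FA2G1,7.77,8.13,N4H4F1
M4A1G1,8.22,8.58,N3H5
M7+M8,8.67,9.03,N2H7;N2H8
A2G2,9.12,9.48,N4H5
FA2G2,9.57,9.93,N4H5F1
A3G1,10.02,10.38,N5H4
FA3G1,10.47,10.83,N5H4F1
A3G2,10.92,11.28,N5H5
FA3G2,11.37,11.73,N5H5F1
F2A3G2+F2A3G3,11.82,12.18,N5H5F2;N5H6F2
A3G3,12.27,12.63,N5H6
FA3G3,12.72,13.08,N5H6F1
A4G3,13.17,13.53,N6H6
A4G4,13.62,13.98,N6H7
FA4G4,14.07,14.43,N6H7F1
F2A4G4+F3A4G4,14.52,14.88,N6H7F2;N6H7F3
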