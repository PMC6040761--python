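# Synthetic 46-analyte serum/plasma N-glycan panel (default fixture).
# Constrained by the published marginals (class counts, trait means, calibrant
# and GLYCOV membership) but the per-analyte reference medians are synthetic;
# replace with a laboratory panel CSV of the same layout to use real values.
# reference_intensity is in percent of total glycans (renormalized on load).
analyte_label,hex,hexnac,fuc,neuac,class,antennae,in_glycov_numerator,in_glycov_denominator,reference_intensity
N2H5,5,2,0,0,oligomannose,0,0,1,3.0
N2H6,6,2,0,0,oligomannose,0,0,1,1.6
N2H7,7,2,0,0,oligomannose,0,0,1,0.8
N2H8,8,2,0,0,oligomannose,0,0,1,0.4
N3H5,5,3,0,0,hybrid,1,0,0,0.25
N3H5S1,5,3,0,1,hybrid,1,0,0,0.3
N3H6,6,3,0,0,hybrid,1,0,0,0.15
N3H3,3,3,0,0,complex,1,0,0,0.4
N3H4,4,3,0,0,complex,1,0,0,0.6
N3H4F1,4,3,1,0,complex,1,0,0,0.7
N3H4S1,4,3,0,1,complex,1,0,0,5.2
N4H3,3,4,0,0,complex,2,0,0,0.5
N4H5,5,4,0,0,complex,2,0,0,1.0
N4H3F1,3,4,1,0,complex,2,0,0,0.6
N4H4F1,4,4,1,0,complex,2,0,0,0.8
N4H5F1,5,4,1,0,complex,2,0,0,3.0
N4H4S1,4,4,0,1,complex,2,0,0,1.2
N4H5S1,5,4,0,1,complex,2,0,0,11.0
N4H5S2,5,4,0,2,complex,2,0,0,38.0
N4H4F1S1,4,4,1,1,complex,2,0,0,0.5
N4H5F1S1,5,4,1,1,complex,2,0,0,5.5
N4H5F1S2,5,4,1,2,complex,2,0,0,10.4
N5H4,4,5,0,0,complex,3,0,0,0.2
N5H4F1,4,5,1,0,complex,3,0,0,0.3
N5H5F2,5,5,2,0,complex,3,0,0,0.3
N5H6F1,6,5,1,0,complex,3,0,0,0.4
N5H5S1,5,5,0,1,complex,3,0,0,0.3
N5H6S1,6,5,0,1,complex,3,0,0,0.8
N5H5S2,5,5,0,2,complex,3,0,0,0.3
N5H6S2,6,5,0,2,complex,3,0,0,2.6
N5H6S3,6,5,0,3,complex,3,1,0,1.8
N5H5F1S1,5,5,1,1,complex,3,0,0,0.4
N5H6F1S1,6,5,1,1,complex,3,0,0,0.5
N5H6F1S2,6,5,1,2,complex,3,0,0,0.7
N5H6F1S3,6,5,1,3,complex,3,0,0,1.0
N5H6F2S3,6,5,2,3,complex,3,1,0,0.5
N6H6S3,6,6,0,3,complex,4,0,0,0.05
N6H7S2,7,6,0,2,complex,4,0,0,0.05
N6H7S3,7,6,0,3,complex,4,0,0,0.1
N6H7S4,7,6,0,4,complex,4,0,0,0.2
N6H7F1S2,7,6,1,2,complex,4,0,0,0.05
N6H7F1S3,7,6,1,3,complex,4,1,0,0.1
N6H7F2S3,7,6,2,3,complex,4,1,0,0.05
N6H7F1S4,7,6,1,4,complex,4,1,0,0.15
N6H7F2S4,7,6,2,4,complex,4,1,0,0.1
N6H7F3S4,7,6,3,4,complex,4,1,0,0.05
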