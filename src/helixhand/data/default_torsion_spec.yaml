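# Default synthetic torsion-profile generator parameters.
#
# Each class lists subpopulations that are cycled in order (two tract
# positions for LHG4 guanosines; the syn-G / anti-C dinucleotide step for
# Z-DNA).  Each angle is a mixture of wrapped-normal components given as
# [mean_deg, sd_deg, weight].
#
# Means/ranges anchored to the reported class-conditional distributions:
#   LHG4  guanosine alpha 150-200 centred at 180; beta mostly > 150;
#         epsilon/zeta bimodal across the two tract positions; chi anti.
#   RHG4  guanosine alpha 250-325 peaking at 300; broad spread elsewhere.
#   ZDNA  cytidine alpha 150-200 peaking at 180, chi anti (~240);
#         guanosine chi syn (~60), alpha below 200.
#   BDNA  alpha 240-360 (mean 300); canonical B-form means elsewhere.
# Standard deviations are back-solved so ~95% of each component's mass
# falls inside its stated range; angles with no reported range get broad
# class-typical components that are not meant to drive classification.
#
# Sample counts default to the curated-structure dataset sizes
# (125 / 88 / 76 / 175 nucleotides).
classes:
  LHG4:
    n_samples: 125
    subpopulations:
      - name: tract-guanosine-1
        base: G
        tract_position: 1
        angles:
          alpha:   [[180.0, 12.5, 1.0]]
          beta:    [[210.0, 18.0, 1.0]]
          gamma:   [[55.0, 15.0, 1.0]]
          delta:   [[140.0, 12.0, 1.0]]
          epsilon: [[210.0, 10.0, 1.0]]
          zeta:    [[255.0, 12.0, 1.0]]
          chi:     [[240.0, 12.0, 1.0]]
      - name: tract-guanosine-2
        base: G
        tract_position: 2
        angles:
          alpha:   [[180.0, 12.5, 1.0]]
          beta:    [[210.0, 18.0, 1.0]]
          gamma:   [[55.0, 15.0, 1.0]]
          delta:   [[140.0, 12.0, 1.0]]
          epsilon: [[260.0, 10.0, 1.0]]
          zeta:    [[305.0, 15.0, 1.0]]
          chi:     [[240.0, 12.0, 1.0]]
  RHG4:
    n_samples: 88
    subpopulations:
      - name: tetrad-guanosine
        base: G
        angles:
          alpha:   [[300.0, 18.0, 1.0]]
          beta:    [[185.0, 40.0, 1.0]]
          gamma:   [[55.0, 30.0, 1.0]]
          delta:   [[130.0, 25.0, 1.0]]
          epsilon: [[215.0, 35.0, 1.0]]
          zeta:    [[255.0, 35.0, 1.0]]
          chi:     [[250.0, 25.0, 1.0]]
  ZDNA:
    n_samples: 76
    subpopulations:
      - name: syn-guanosine
        base: G
        angles:
          alpha:   [[65.0, 15.0, 1.0]]
          beta:    [[185.0, 15.0, 1.0]]
          gamma:   [[180.0, 15.0, 1.0]]
          delta:   [[95.0, 10.0, 1.0]]
          epsilon: [[245.0, 15.0, 1.0]]
          zeta:    [[75.0, 15.0, 1.0]]
          chi:     [[60.0, 12.0, 1.0]]
      - name: anti-cytidine
        base: C
        angles:
          alpha:   [[180.0, 12.5, 1.0]]
          beta:    [[230.0, 15.0, 1.0]]
          gamma:   [[55.0, 12.0, 1.0]]
          delta:   [[140.0, 10.0, 1.0]]
          epsilon: [[265.0, 12.0, 1.0]]
          zeta:    [[80.0, 15.0, 1.0]]
          chi:     [[240.0, 12.0, 1.0]]
  BDNA:
    n_samples: 175
    subpopulations:
      - name: purine
        base: G
        angles:
          alpha:   [[300.0, 25.0, 1.0]]
          beta:    [[175.0, 25.0, 1.0]]
          gamma:   [[55.0, 20.0, 1.0]]
          delta:   [[125.0, 20.0, 1.0]]
          epsilon: [[190.0, 20.0, 1.0]]
          zeta:    [[265.0, 20.0, 1.0]]
          chi:     [[250.0, 20.0, 1.0]]
      - name: pyrimidine
        base: C
        angles:
          alpha:   [[300.0, 25.0, 1.0]]
          beta:    [[175.0, 25.0, 1.0]]
          gamma:   [[55.0, 20.0, 1.0]]
          delta:   [[125.0, 20.0, 1.0]]
          epsilon: [[190.0, 20.0, 1.0]]
          zeta:    [[265.0, 20.0, 1.0]]
          chi:     [[250.0, 20.0, 1.0]]
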