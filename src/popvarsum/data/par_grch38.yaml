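# Pseudoautosomal regions for the GRCh38 reference assembly.
# Intervals are 0-based half-open, derived from the GRC-published 1-based
# inclusive coordinates (X PAR1 10,001-2,781,479; X PAR2 155,701,383-156,030,895;
# Y PAR1 10,001-2,781,479; Y PAR2 56,887,903-57,217,415).
name: grch38
chromosomes:
  "1": 248956422
  "2": 242193529
  "3": 198295559
  "4": 190214555
  "5": 181538259
  "6": 170805979
  "7": 159345973
  "8": 145138636
  "9": 138394717
  "10": 133797422
  "11": 135086622
  "12": 133275309
  "13": 114364328
  "14": 107043718
  "15": 101991189
  "16": 90338345
  "17": 83257441
  "18": 80373285
  "19": 58617616
  "20": 64444167
  "21": 46709983
  "22": 50818468
  X: 156040895
  Y: 57227415
  MT: 16569
par:
  X:
    - [10000, 2781479]
    - [155701382, 156030895]
  Y:
    - [10000, 2781479]
    - [56887902, 57217415]
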