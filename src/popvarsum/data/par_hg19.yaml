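# Pseudoautosomal regions for the hg19 / GRCh37 reference assembly.
# Intervals are 0-based half-open, derived from the GRC-published 1-based
# inclusive coordinates (X PAR1 60,001-2,699,520; X PAR2 154,931,044-155,260,560;
# Y PAR1 10,001-2,649,520; Y PAR2 59,034,050-59,363,566).
name: hg19
chromosomes:
  "1": 249250621
  "2": 243199373
  "3": 198022430
  "4": 191154276
  "5": 180915260
  "6": 171115067
  "7": 159138663
  "8": 146364022
  "9": 141213431
  "10": 135534747
  "11": 135006516
  "12": 133851895
  "13": 115169878
  "14": 107349540
  "15": 102531392
  "16": 90354753
  "17": 81195210
  "18": 78077248
  "19": 59128983
  "20": 63025520
  "21": 48129895
  "22": 51304566
  X: 155270560
  Y: 59373566
  MT: 16569
par:
  X:
    - [60000, 2699520]
    - [154931043, 155260560]
  Y:
    - [10000, 2649520]
    - [59034049, 59363566]
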