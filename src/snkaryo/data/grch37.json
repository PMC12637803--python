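{
  "assembly_id": "GRCh37",
  "comment": "Autosome + X lengths and centromere intervals (0-based half-open) from the GRCh37/hg19 reference and its gap annotation.",
  "chromosomes": [
    {"name": "1",  "length": 249250621, "centromere": [121535434, 124535434]},
    {"name": "2",  "length": 243199373, "centromere": [92326171, 95326171]},
    {"name": "3",  "length": 198022430, "centromere": [90504854, 93504854]},
    {"name": "4",  "length": 191154276, "centromere": [49660117, 52660117]},
    {"name": "5",  "length": 180915260, "centromere": [46405641, 49405641]},
    {"name": "6",  "length": 171115067, "centromere": [58830166, 61830166]},
    {"name": "7",  "length": 159138663, "centromere": [58054331, 61054331]},
    {"name": "8",  "length": 146364022, "centromere": [43838887, 46838887]},
    {"name": "9",  "length": 141213431, "centromere": [47367679, 50367679]},
    {"name": "10", "length": 135534747, "centromere": [39254935, 42254935]},
    {"name": "11", "length": 135006516, "centromere": [51644205, 54644205]},
    {"name": "12", "length": 133851895, "centromere": [34856694, 37856694]},
    {"name": "13", "length": 115169878, "centromere": [16000000, 19000000]},
    {"name": "14", "length": 107349540, "centromere": [16000000, 19000000]},
    {"name": "15", "length": 102531392, "centromere": [17000000, 20000000]},
    {"name": "16", "length": 90354753,  "centromere": [35335801, 38335801]},
    {"name": "17", "length": 81195210,  "centromere": [22263006, 25263006]},
    {"name": "18", "length": 78077248,  "centromere": [15460898, 18460898]},
    {"name": "19", "length": 59128983,  "centromere": [24681782, 27681782]},
    {"name": "20", "length": 63025520,  "centromere": [26369569, 29369569]},
    {"name": "21", "length": 48129895,  "centromere": [11288129, 14288129]},
    {"name": "22", "length": 51304566,  "centromere": [13000000, 16000000]},
    {"name": "X",  "length": 155270560, "centromere": [58632012, 61632012]}
  ],
  "acrocentric": ["13", "14", "15", "21", "22"]
}
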