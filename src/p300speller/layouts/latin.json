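[
 ["A", "B", "C", "D", "E", "F"],
 ["G", "H", "I", "J", "K", "L"],
 ["M", "N", "O", "P", "Q", "R"],
 ["S", "T", "U", "V", "W", "X"],
 ["Y", "Z", "1", "2", "3", "4"],
 ["5", "6", "7", "8", "_", "¶"]
]
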