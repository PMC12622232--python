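{
  "blastp": {
    "tool": "blastp",
    "dialect": "blast",
    "prepare": [],
    "command": ["blastp", "-query", "{query}", "-subject", "{subject}", "-evalue", "1e-5", "-outfmt", "6", "-out", "{out}"]
  },
  "blastpdb": {
    "tool": "blastp",
    "dialect": "blast",
    "prepare": [["makeblastdb", "-in", "{subject}", "-dbtype", "prot", "-out", "{db}"]],
    "command": ["blastp", "-query", "{query}", "-db", "{db}", "-evalue", "1e-5", "-outfmt", "6", "-out", "{out}"]
  },
  "diamond_fast": {
    "tool": "diamond",
    "dialect": "diamond",
    "prepare": [["diamond", "makedb", "--in", "{subject}", "--db", "{db}"]],
    "command": ["diamond", "blastp", "--fast", "--query", "{query}", "--db", "{db}", "--evalue", "1e-5", "--outfmt", "6", "--out", "{out}"]
  },
  "diamond_sensitive": {
    "tool": "diamond",
    "dialect": "diamond",
    "prepare": [["diamond", "makedb", "--in", "{subject}", "--db", "{db}"]],
    "command": ["diamond", "blastp", "--sensitive", "--query", "{query}", "--db", "{db}", "--evalue", "1e-5", "--outfmt", "6", "--out", "{out}"]
  },
  "diamond_verysensitive": {
    "tool": "diamond",
    "dialect": "diamond",
    "prepare": [["diamond", "makedb", "--in", "{subject}", "--db", "{db}"]],
    "command": ["diamond", "blastp", "--very-sensitive", "--query", "{query}", "--db", "{db}", "--evalue", "1e-5", "--outfmt", "6", "--out", "{out}"]
  },
  "diamond_ultrasensitive": {
    "tool": "diamond",
    "dialect": "diamond",
    "prepare": [["diamond", "makedb", "--in", "{subject}", "--db", "{db}"]],
    "command": ["diamond", "blastp", "--ultra-sensitive", "--query", "{query}", "--db", "{db}", "--evalue", "1e-5", "--outfmt", "6", "--out", "{out}"]
  },
  "mmseqs2_s1dot0": {
    "tool": "mmseqs",
    "dialect": "mmseqs2",
    "prepare": [],
    "command": ["mmseqs", "easy-search", "{query}", "{subject}", "{out}", "{tmpdir}", "-s", "1.0", "-e", "1e-5"]
  },
  "mmseqs2_s2dot5": {
    "tool": "mmseqs",
    "dialect": "mmseqs2",
    "prepare": [],
    "command": ["mmseqs", "easy-search", "{query}", "{subject}", "{out}", "{tmpdir}", "-s", "2.5", "-e", "1e-5"]
  },
  "mmseqs2_s6dot0": {
    "tool": "mmseqs",
    "dialect": "mmseqs2",
    "prepare": [],
    "command": ["mmseqs", "easy-search", "{query}", "{subject}", "{out}", "{tmpdir}", "-s", "6.0", "-e", "1e-5"]
  },
  "mmseqs2_s7dot5": {
    "tool": "mmseqs",
    "dialect": "mmseqs2",
    "prepare": [],
    "command": ["mmseqs", "easy-search", "{query}", "{subject}", "{out}", "{tmpdir}", "-s", "7.5", "-e", "1e-5"]
  }
}
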