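{
 "format": "treebase-net-v1",
 "name": "fig4_wheat",
 "comment": "Bread-wheat network: five leaves, three reticulations. a=Triticum urartu, b=Triticum turgidum, c=Triticum aestivum, d=Aegilops tauschii, e=Aegilops speltoides. hd = homoploid hybrid ancestor of d (A and B lineages), hb = tetraploid ancestor of b, hc = hexaploid ancestor of c (from the b and d lineages).",
 "vertices": [
  {
   "id": "A1"
  },
  {
   "id": "A2"
  },
  {
   "id": "B1"
  },
  {
   "id": "B2"
  },
  {
   "id": "a",
   "label": "a"
  },
  {
   "id": "b",
   "label": "b"
  },
  {
   "id": "c",
   "label": "c"
  },
  {
   "id": "d",
   "label": "d"
  },
  {
   "id": "e",
   "label": "e"
  },
  {
   "id": "hb"
  },
  {
   "id": "hc"
  },
  {
   "id": "hd"
  },
  {
   "id": "pb"
  },
  {
   "id": "pd"
  },
  {
   "id": "rho"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "A1"
  },
  {
   "id": "e01",
   "source": "rho",
   "target": "B1"
  },
  {
   "id": "e02",
   "source": "A1",
   "target": "A2"
  },
  {
   "id": "e03",
   "source": "A1",
   "target": "hd"
  },
  {
   "id": "e04",
   "source": "A2",
   "target": "a"
  },
  {
   "id": "e05",
   "source": "A2",
   "target": "hb"
  },
  {
   "id": "e06",
   "source": "B1",
   "target": "B2"
  },
  {
   "id": "e07",
   "source": "B1",
   "target": "hd"
  },
  {
   "id": "e08",
   "source": "B2",
   "target": "e"
  },
  {
   "id": "e09",
   "source": "B2",
   "target": "hb"
  },
  {
   "id": "e10",
   "source": "hd",
   "target": "pd"
  },
  {
   "id": "e11",
   "source": "pd",
   "target": "d"
  },
  {
   "id": "e12",
   "source": "pd",
   "target": "hc"
  },
  {
   "id": "e13",
   "source": "hb",
   "target": "pb"
  },
  {
   "id": "e14",
   "source": "pb",
   "target": "b"
  },
  {
   "id": "e15",
   "source": "pb",
   "target": "hc"
  },
  {
   "id": "e16",
   "source": "hc",
   "target": "c"
  }
 ]
}
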