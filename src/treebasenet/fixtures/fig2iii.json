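{
 "format": "treebase-net-v1",
 "name": "fig2iii",
 "comment": "Tree-based despite first appearances: tree arcs (u,x) and (x,v); linking arcs (u,v) and (w,x).",
 "vertices": [
  {
   "id": "a",
   "label": "a"
  },
  {
   "id": "b",
   "label": "b"
  },
  {
   "id": "rho"
  },
  {
   "id": "u"
  },
  {
   "id": "v"
  },
  {
   "id": "w"
  },
  {
   "id": "x"
  }
 ],
 "arcs": [
  {
   "id": "e00",
   "source": "rho",
   "target": "u"
  },
  {
   "id": "e01",
   "source": "rho",
   "target": "w"
  },
  {
   "id": "e02",
   "source": "u",
   "target": "x"
  },
  {
   "id": "e03",
   "source": "u",
   "target": "v"
  },
  {
   "id": "e04",
   "source": "w",
   "target": "x"
  },
  {
   "id": "e05",
   "source": "w",
   "target": "b"
  },
  {
   "id": "e06",
   "source": "x",
   "target": "v"
  },
  {
   "id": "e07",
   "source": "v",
   "target": "a"
  }
 ]
}
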