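...................................................................
...................................................................
...................................................................
...................................................................
...................................................................
........................................o..........................
...................................................................
...................................................................
................................o..................................
...................................................................
..............................................................o....
....................................................o..............
.......................o.......................o..............o....
......oo.o..............o.o........................................
.........o..........................o.........o....................
...................................................................
...............................o...................................
..................................o.............o..................
......o............o...............................................
.................................o..................o..............
...................................................................
...................................................o......o........
........o......................o...................................
..........o........................................................
...................................................................
...........o........................o..............................
...................................................................
...................................................................
..........................................................o........
..................................................o................
....o.....................o........................................
...................................................o.o.............
...c..ccc..c..c............c..........c......c....cc..c..c.........
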