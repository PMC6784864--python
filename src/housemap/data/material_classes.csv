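component,code,material_class
floor,earth,natural
floor,sand,natural
floor,dung,natural
floor,wood planks,rudimentary
floor,palm,rudimentary
floor,bamboo,rudimentary
floor,parquet,finished
floor,vinyl,finished
floor,ceramic tiles,finished
floor,cement,finished
floor,carpet,finished
roof,no roof,natural
roof,thatch,natural
roof,palm leaf,natural
roof,sod,natural
roof,rustic mat,rudimentary
roof,palm bamboo,rudimentary
roof,wood planks,rudimentary
roof,cardboard,rudimentary
roof,metal,finished
roof,wood,finished
roof,calamine,finished
roof,ceramic tiles,finished
roof,cement,finished
roof,roofing shingles,finished
wall,no walls,natural
wall,cane palm trunks,natural
wall,dirt,natural
wall,bamboo with mud,rudimentary
wall,stone with mud,rudimentary
wall,uncovered adobe,rudimentary
wall,plywood,rudimentary
wall,cardboard,rudimentary
wall,reused wood,rudimentary
wall,cement,finished
wall,stone with lime cement,finished
wall,bricks,finished
wall,cement blocks,finished
wall,covered adobe,finished
wall,wood planks shingles,finished
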