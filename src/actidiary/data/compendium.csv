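activity,intensity,code,met
resting,any,07030,1.0
sleeping,any,07030,0.95
lying quietly,any,07020,1.3
eating,any,13030,1.5
sitting,mild,07021,1.3
sitting,moderate,09055,1.5
sitting,vigorous,09055,1.8
watching tv,mild,07020,1.3
watching tv,moderate,07020,1.3
watching tv,vigorous,07020,1.5
reading,any,09030,1.3
computer work,any,09040,1.5
standing,mild,07040,1.3
standing,moderate,07041,1.8
standing,vigorous,07041,2.5
walking,mild,17151,2.0
walking,moderate,17170,3.5
walking,vigorous,17200,5.0
walking the dog,mild,17165,2.8
walking the dog,moderate,17165,3.0
walking the dog,vigorous,17165,4.0
nordic walking,any,17172,4.8
hiking,moderate,17080,5.3
hiking,vigorous,17082,6.5
jogging,any,12020,7.0
running,moderate,12030,8.0
running,vigorous,12050,10.0
cycling,mild,01011,3.5
cycling,moderate,01015,6.8
cycling,vigorous,01040,8.5
stationary cycling,mild,02011,3.5
stationary cycling,moderate,02012,6.8
stationary cycling,vigorous,02013,8.8
housekeeping,mild,05040,2.3
housekeeping,moderate,05035,3.3
housekeeping,vigorous,05030,3.8
cleaning,mild,05040,2.3
cleaning,moderate,05020,3.3
cleaning,vigorous,05021,3.8
cooking,mild,05049,2.0
cooking,moderate,05049,2.5
cooking,vigorous,05051,3.3
washing dishes,any,05041,1.8
laundry,any,05070,2.0
ironing,any,05070,1.8
vacuuming,any,05043,3.3
making bed,any,05110,2.0
gardening,mild,08245,2.3
gardening,moderate,08245,3.8
gardening,vigorous,08050,5.0
mowing lawn,any,08120,5.5
raking,any,08130,3.8
shoveling snow,any,08200,5.3
tinkering,any,06235,3.0
doing crafts,any,09100,1.8
carpentry,any,06050,3.0
shopping,mild,05060,2.3
shopping,moderate,05060,2.3
shopping,vigorous,05065,3.5
grocery shopping,any,05060,2.3
visiting friends,any,07050,1.5
playing cards,any,09065,1.5
playing music,any,10074,2.0
dancing,mild,03015,3.0
dancing,moderate,03025,4.5
dancing,vigorous,03021,7.3
swimming,mild,18310,4.8
swimming,moderate,18240,5.8
swimming,vigorous,18230,8.3
gymnastics,mild,15300,2.8
gymnastics,moderate,15300,3.8
gymnastics,vigorous,15310,5.5
stretching,any,15600,2.3
yoga,any,15610,2.5
strength training,moderate,02054,3.5
strength training,vigorous,02050,6.0
table tennis,any,15660,4.0
bowling,any,15090,3.0
golf,any,15270,4.8
car driving,any,16010,2.5
car passenger,any,16015,1.3
motorbike riding,any,16030,3.5
train passenger,any,16016,1.3
bus passenger,any,16016,1.3
climbing stairs,any,17133,4.0
personal care,any,13040,2.0
showering,any,13045,2.0
dressing,any,13000,2.5
physiotherapy,any,15300,3.5
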