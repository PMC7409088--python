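item_id,domain,label,n_categories
PL1,PL,Playing imaginary games,4
PL2,PL,Playing a game with rules,4
PL3,PL,Keeping up with other children while playing,4
SC1,SC,Making contact with other children,4
SC2,SC,Doing activities with peers without visual impairment,4
SC3,SC,Playing outdoors with friends,4
SC4,SC,Playing at a friend's house,4
SC5,SC,Inviting a friend to play at your house,4
SC6,SC,Participating in group activities,4
MO1,MO,Cycling,4
MO2,MO,Doing activities with speed,4
MO3,MO,Participating in traffic independently,4
MO4,MO,Learning new routes,4
LT1,LT,Reading books,4
LT2,LT,Using social media,4
LT3,LT,"Playing games on computer, tablet, phone",4
LT4,LT,Watching films/television,4
LT5,LT,Going to a club/association independently,4
LT6,LT,Participating at a club/association,4
LT7,LT,Making music,4
LT8,LT,Performing a hobby,4
CO1,CO,Expressing in words properly,4
CO2,CO,Asking questions,4
CO3,CO,Talking about feelings,4
CO4,CO,Sharing events,4
CO5,CO,Participating in a conversation,4
CO6,CO,Asking help from familiar people,4
CO7,CO,Asking help from unfamiliar people,4
CO8,CO,Indicating what can (not) be seen,4
CO9,CO,Estimating feelings of other children,4
CO10,CO,Estimating the distance to others,4
CO11,CO,Stating that you want to join in a group,4
CO12,CO,Dealing with bullying,4
SL1,SL,Finding the way in school,4
SL2,SL,Keeping overview in class,4
SL3,SL,Keeping up with classmates,4
SL4,SL,Reading the slide board or schoolboard,4
SL5,SL,Writing,4
SL6,SL,Reading braille,4
SL7,SL,Finding information,4
SL8,SL,Finding school stuff in the closet/drawer,4
SL9,SL,Cooperating with other children,4
SL10,SL,Participating in physical education,4
SL11,SL,Maintaining energy levels for fun activities,4
SR1,SR,Eating with fork and knife,4
SR2,SR,Making a sandwich,4
SR3,SR,Brushing your teeth independently,4
SR4,SR,Going to the toilet,4
SR5,SR,Bathing/showering independently,4
AC1,AC,Telling others about your visual impairment,4
AC2,AC,Dealing with incapability,4
AC3,AC,Dealing with making mistakes,4
AC4,AC,Empathizing with others,4
AC5,AC,Using visual aids,4
FI1,FI,Recognizing money,4
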